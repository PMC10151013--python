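"""Published per-call pain reports of the source 20-participant, 7-day
knee-OA wearable study, plus a loader for its deposited per-call-period
impedance tables.

The deposited reduced data (one row per kept call period with the 128 kHz
per-length resistance mean/CV and 40 kHz per-length reactance mean/CV, for
each electrode configuration) are not redistributed here; to run the
reproduction targets, convert them to CSV files::

    data/supplementary/longitudinal.csv
    data/supplementary/transverse.csv

with columns ``participant_id`` (integer 1-20), ``group`` (0 control, 1 OA),
``day`` (1-7), ``call`` (1-4), ``plr128_mean``, ``plr128_cv``,
``plx40_mean``, ``plx40_cv``.  Pain outcomes are attached from the published
per-call summary below.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .reduction import binarize_pain

#: Published ESM pain summary: participant -> day -> per-call 0-4 ratings, or
#: "X" meaning pain was reported between calls but not at any call.
#: Participants who never reported pain are absent (all their calls are 0).
#: Cells marked with '*' in the publication (pain reported but no paired
#: impedance data) are included; the pairing step drops them naturally.
PAIN_REPORTS: dict[int, dict[int, tuple | str]] = {
    1: {2: (0, 0, 0, 1)},
    3: {5: (2, 0, 0, 0)},
    4: {4: (0, 0, 0, 1)},
    9: {2: "X", 3: "X", 4: "X", 6: "X", 7: "X"},
    10: {3: "X", 6: (1, 0, 0, 0)},
    11: {2: (2, 0, 0, 0), 7: "X"},
    15: {1: (0, 3, 0, 3), 2: (0, 1, 0, 0), 3: (3, 2, 2, 0), 4: (0, 1, 2, 1),
         6: (3, 0, 2, 0), 7: (1, 1, 2, 0)},
    16: {1: (1, 1, 0, 0), 2: (2, 0, 2, 3), 3: (3, 2, 0, 1), 4: (0, 1, 1, 2),
         5: (0, 3, 2, 3), 6: (0, 0, 1, 1), 7: (0, 2, 2, 3)},
    17: {1: (1, 0, 0, 0), 5: "X"},
    18: {1: "X", 6: "X"},
}

#: participants reported as belonging to the OA group in the pain summary
OA_PARTICIPANTS = {1, 4, 9, 10, 11, 15, 16, 17, 18}


def pain_binary(participant: int, day: int, call: int,
                mode: str = "momentary") -> int:
    """Binary pain outcome for one call period of the published study."""
    cell = PAIN_REPORTS.get(int(participant), {}).get(int(day))
    if cell is None:
        return 0
    if cell == "X":
        return binarize_pain(0, "yes", mode)
    return binarize_pain(cell[int(call) - 1], "no", mode)


def attach_pain(table: pd.DataFrame, mode: str = "momentary") -> pd.DataFrame:
    """Add the published binary pain outcome to a deposited-data table."""
    out = table.copy()
    out["pain"] = [
        pain_binary(r.participant_id, r.day, r.call, mode)
        for r in out.itertuples()
    ]
    return out


def supplementary_paths(root) -> dict[str, Path]:
    root = Path(root)
    return {
        "long": root / "data" / "supplementary" / "longitudinal.csv",
        "trans": root / "data" / "supplementary" / "transverse.csv",
    }


def load_supplementary(path, configuration: str,
                       mode: str = "momentary") -> pd.DataFrame:
    """Load one deposited table into the pipeline's reduced-metrics layout."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"participant_id", "group", "day", "call",
                "plr128_mean", "plr128_cv", "plx40_mean", "plx40_cv"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"supplementary table missing columns: {sorted(missing)}")
    df["config"] = configuration
    return attach_pain(df, mode)
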