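"""Conditional pain-probability curves and per-call-period timelines."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit  # noqa: F401  (logit re-exported for callers)

from .glmm import ModelFit

_METRIC_COLUMNS = {"r128": "plr128_mean", "x40": "plx40_mean"}


@dataclass
class ProbabilityCurve:
    """Logistic mapping from a per-length metric (ohm/m) to pain probability.

    ``valid_range`` is the metric range observed while fitting; evaluating
    outside it warns (extrapolation) but still returns the logistic value.
    """

    beta0: float
    beta1: float
    metric: str = "r128"
    valid_range: tuple[float, float] | None = None

    @classmethod
    def from_fit(cls, fitted: ModelFit, data: pd.DataFrame | None = None):
        """Curve from a fitted model's intercept and metric-mean slope.

        Intended for the OA-subset model whose only continuous effect of
        interest is the metric mean; other covariates are ignored (their
        values are effectively folded into the intercept at zero).
        """
        beta0 = fitted.coefficients["intercept"]
        beta1 = fitted.coefficients["plz_mean"]
        vr = None
        if data is not None:
            col = _METRIC_COLUMNS[fitted.spec.metric]
            vals = data[col].dropna()
            if len(vals):
                vr = (float(vals.min()), float(vals.max()))
        return cls(beta0=beta0, beta1=beta1, metric=fitted.spec.metric,
                   valid_range=vr)


def probability(curve: ProbabilityCurve, value) -> float | np.ndarray:
    """``logistic(beta0 + beta1 * value)``; warns outside the fitted range."""
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("metric value must be finite")
    if curve.valid_range is not None:
        lo, hi = curve.valid_range
        if np.any(arr < lo) or np.any(arr > hi):
            warnings.warn(
                f"value outside fitted range [{lo:g}, {hi:g}]; extrapolating"
            )
    out = expit(curve.beta0 + curve.beta1 * arr)
    return float(out) if np.ndim(value) == 0 else out


def timeline(
    curve: ProbabilityCurve,
    reduced: pd.DataFrame,
    participant_id,
    configuration: str = "trans",
) -> pd.DataFrame:
    """Per-call-period probabilities for one participant, in call order.

    Returns a frame (day, call, value, probability); empty with a warning
    when the participant has no kept periods for the requested configuration.
    """
    col = _METRIC_COLUMNS[curve.metric]
    sub = reduced[
        (reduced["participant_id"] == participant_id)
        & (reduced.get("config", configuration) == configuration)
    ].dropna(subset=[col])
    if len(sub) == 0:
        warnings.warn(f"no kept call periods for participant {participant_id}")
        return pd.DataFrame(columns=["day", "call", "value", "probability"])
    sub = sub.sort_values(["day", "call"], kind="stable")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # range warning per point is noise here
        probs = probability(curve, sub[col].to_numpy())
    return pd.DataFrame(
        {
            "day": sub["day"].to_numpy(),
            "call": sub["call"].to_numpy(),
            "value": sub[col].to_numpy(),
            "probability": probs,
        }
    )


def group_contrast(
    reduced: pd.DataFrame,
    metric: str = "r128",
    subset: str = "all",
) -> pd.DataFrame:
    """Metric means by (group, pain) cell; missing cells are reported as NaN.

    With ``subset="oa_only"`` only OA-group periods enter, mirroring the
    within-OA pain vs no-pain comparison.
    """
    col = _METRIC_COLUMNS[metric]
    df = reduced.dropna(subset=[col, "pain"])
    if subset == "oa_only":
        df = df[df["group"] == 1]
    groups = sorted(df["group"].unique()) if len(df) else []
    rows = []
    for grp in groups:
        for pain in (0, 1):
            cell = df[(df["group"] == grp) & (df["pain"] == pain)]
            rows.append(
                {
                    "group": grp,
                    "pain": pain,
                    "mean": float(cell[col].mean()) if len(cell) else float("nan"),
                    "n": len(cell),
                    "missing": len(cell) == 0,
                }
            )
    return pd.DataFrame(rows, columns=["group", "pain", "mean", "n", "missing"])
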