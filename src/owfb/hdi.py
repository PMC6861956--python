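"""The Hypertension Diagnosis Index (HDI).

A single linear score per epoch built from the six top-ranked sub-band
features:

    HDI = 6 - (3 * LOGE_SB2 + 4 * LOGE_SB3 + SFD_SB6)
            - 15 * (SFD_SB2 + SFD_SB3 + SFD_SB4)

evaluated verbatim as published.  Note a documented inconsistency: at the
published per-class feature means this formula yields values near -164,
far outside the published per-class decision ranges (LRHT 1.501-2.355,
HRHT 2.774-6.084); the printed equation is likely a typeset corruption of
a rescaled form.  It is implemented exactly as printed and NOT silently
repaired; a custom :class:`HDIFormula` (coefficients + intercept) can be
substituted without code changes.

Classification assigns an epoch to a class when its index falls inside
that class's configured range; values in neither range are
``indeterminate`` unless a scalar two-way threshold is configured instead
(default midpoint of the gap between the published ranges, 2.5645).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "HDI_FEATURES",
    "HDIFormula",
    "DEFAULT_FORMULA",
    "DEFAULT_RANGES",
    "DEFAULT_THRESHOLD",
    "HDIResult",
    "compute_hdi",
    "classify",
    "hdi_table",
]

HDI_FEATURES = (
    "LOGE_SB2",
    "LOGE_SB3",
    "SFD_SB6",
    "SFD_SB2",
    "SFD_SB3",
    "SFD_SB4",
)

#: Published per-class index ranges.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "lrht": (1.501, 2.355),
    "hrht": (2.774, 6.084),
}

#: Midpoint of the gap between the published ranges (two-way split).
DEFAULT_THRESHOLD = 2.5645


@dataclass(frozen=True)
class HDIFormula:
    """An affine index: ``intercept + sum(coefficients[f] * value[f])``."""

    intercept: float
    coefficients: dict[str, float]

    def __call__(self, features: dict[str, float]) -> float:
        total = self.intercept
        for name, coef in self.coefficients.items():
            v = features[name]
            if not math.isfinite(v):
                raise ValueError(f"non-finite feature {name} = {v!r}")
            total += coef * v
        return total


DEFAULT_FORMULA = HDIFormula(
    intercept=6.0,
    coefficients={
        "LOGE_SB2": -3.0,
        "LOGE_SB3": -4.0,
        "SFD_SB6": -1.0,
        "SFD_SB2": -15.0,
        "SFD_SB3": -15.0,
        "SFD_SB4": -15.0,
    },
)


@dataclass(frozen=True)
class HDIResult:
    hdi_value: float
    predicted_class: str  # "LRHT" | "HRHT" | "indeterminate"
    inputs_echo: dict[str, float] = field(default_factory=dict)


def compute_hdi(
    features: dict[str, float], formula: HDIFormula = DEFAULT_FORMULA
) -> float:
    """Evaluate the index on a mapping of the six feature values."""
    missing = [n for n in formula.coefficients if n not in features]
    if missing:
        raise KeyError(f"missing feature(s) for HDI: {missing}")
    return formula(features)


def classify(
    hdi_value: float,
    ranges: dict[str, tuple[float, float]] | None = None,
    threshold: float | None = None,
) -> str:
    """Map an index value to LRHT / HRHT / indeterminate.

    With ``threshold`` set, a two-way split at the threshold is used
    instead of the ranges (values below -> LRHT).
    """
    if not math.isfinite(hdi_value):
        raise ValueError(f"non-finite HDI value {hdi_value!r}")
    if threshold is not None:
        return "LRHT" if hdi_value < threshold else "HRHT"
    if ranges is None:
        ranges = DEFAULT_RANGES
    lo_l, hi_l = ranges["lrht"]
    lo_h, hi_h = ranges["hrht"]
    if lo_l > hi_l or lo_h > hi_h:
        raise ValueError("each range must be (low, high) with low <= high")
    if max(lo_l, lo_h) <= min(hi_l, hi_h):
        raise ValueError(f"overlapping class ranges: {ranges}")
    if lo_l <= hdi_value <= hi_l:
        return "LRHT"
    if lo_h <= hdi_value <= hi_h:
        return "HRHT"
    return "indeterminate"


def hdi_table(
    features: pd.DataFrame,
    channel: str | None = "CH3",
    formula: HDIFormula = DEFAULT_FORMULA,
    ranges: dict[str, tuple[float, float]] | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-epoch HDI and predicted class for a feature table.

    ``channel=None`` keeps all channels; the published headline results
    are for CH3 (lead V5), hence the default.
    """
    df = features if channel is None else features[features["channel"] == channel]
    values = [
        compute_hdi({f: row[f] for f in formula.coefficients}, formula)
        for _, row in df.iterrows()
    ]
    out = df[["subject_id", "epoch_index", "channel", "class_label"]].copy()
    out["hdi"] = values
    out["predicted_class"] = [
        classify(v, ranges=ranges, threshold=threshold) for v in values
    ]
    return out.reset_index(drop=True)
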