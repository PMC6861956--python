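"""Two-sample t-test ranking of sub-band features.

Features are ranked by the absolute value of the two-sided Student's
t statistic (pooled variance) between the low-risk (LRHT) and high-risk
(HRHT) classes; p-values come from the t distribution with
``n1 + n2 - 2`` degrees of freedom.  Welch's unequal-variance variant is
available by flag -- with very unequal class sizes it is the statistically
safer choice -- but the pooled test is the default convention here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .hdi import HDI_FEATURES

__all__ = ["t_rank", "select_top"]


def t_rank(
    features: pd.DataFrame,
    class_column: str = "class_label",
    classes: tuple[str, str] = ("LRHT", "HRHT"),
    welch: bool = False,
) -> pd.DataFrame:
    """Rank every feature column by |t| between the two classes.

    Returns a DataFrame with columns (rank, feature, t_value, p_value),
    sorted by |t| descending, ranks 1..n_features.  The t statistic is
    signed as mean(first class) - mean(second class).
    """
    g1 = features[features[class_column] == classes[0]]
    g2 = features[features[class_column] == classes[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(
            f"both classes must have >= 2 rows; got "
            f"{classes[0]}: {len(g1)}, {classes[1]}: {len(g2)}"
        )
    feature_cols = [
        c for c in features.columns
        if c.startswith(("LOGE_", "SFD_"))
    ]
    if not feature_cols:
        raise ValueError("no LOGE_*/SFD_* feature columns found")

    rows = []
    for col in feature_cols:
        x1 = g1[col].to_numpy(dtype=float)
        x2 = g2[col].to_numpy(dtype=float)
        if not welch and x1.var(ddof=1) == 0 and x2.var(ddof=1) == 0:
            warnings.warn(
                f"feature {col}: zero pooled variance; t reported as inf",
                stacklevel=2,
            )
            t = np.inf if x1.mean() != x2.mean() else 0.0
            p = 0.0 if np.isinf(t) else 1.0
        else:
            t, p = stats.ttest_ind(x1, x2, equal_var=not welch)
            t, p = float(t), float(p)
        rows.append({"feature": col, "t_value": t, "p_value": p})
    table = pd.DataFrame(rows)
    table = table.reindex(
        table["t_value"].abs().sort_values(ascending=False, kind="stable").index
    )
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table.reset_index(drop=True)


def select_top(
    rank_table: pd.DataFrame, names: list[str] | None = None
) -> list[str]:
    """Return a feature subset for index construction.

    With ``names=None`` the default is the six diagnostic-index features
    (LOGE of SB2/SB3 and SFD of SB6/SB2/SB3/SB4).  Any caller-specified
    subset is validated against the table.
    """
    available = set(rank_table["feature"])
    if names is None:
        names = list(HDI_FEATURES)
    if not names:
        raise ValueError("empty feature selection")
    missing = [n for n in names if n not in available]
    if missing:
        raise ValueError(f"unknown feature name(s): {missing}")
    return list(names)
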