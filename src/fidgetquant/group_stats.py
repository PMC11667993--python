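"""Between-class comparison of movement features.

Each feature x sampling-rate cell is compared between the two classes with
a two-sample t-test (Welch by default: with fidgeting data the high-movement
class is far more dispersed, so assuming equal variances is unsafe; the
pooled test is available via ``equal_var=True``). No multiple-testing
correction is applied by default; Holm correction is available as a flag.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FEATURE_COLUMNS, FEATURE_NAMES, FeatureRecord
from .errors import ConfigurationError


def two_sample_ttest(
    a: np.ndarray, b: np.ndarray, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test; Welch unless ``equal_var``.

    Degenerate inputs (zero variance in both groups with equal means) return
    (0.0, 1.0) by convention rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each group needs at least 2 observations")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def comparison_table(
    records: Iterable[FeatureRecord] | pd.DataFrame,
    equal_var: bool = False,
    holm: bool = False,
) -> pd.DataFrame:
    """Per (feature x rate) class comparison: mean +- SD per class, t and p.

    Returns one row per feature and sampling rate present in the input
    (3 features x 3 rates = 9 rows for a full three-rate run).
    """
    df = (
        records
        if isinstance(records, pd.DataFrame)
        else pd.DataFrame([r.as_dict() for r in records])
    )
    labels = sorted(df["label"].unique())
    if len(labels) != 2:
        raise ConfigurationError(
            f"comparison needs exactly 2 classes, got {labels}"
        )
    pos, neg = labels[::-1] if "pos" in labels else (labels[0], labels[1])

    rows = []
    for rate_d, grp in df.groupby("rate_d"):
        a_grp = grp[grp["label"] == pos]
        b_grp = grp[grp["label"] == neg]
        for col in FEATURE_COLUMNS:
            a = a_grp[col].to_numpy()
            b = b_grp[col].to_numpy()
            t, p = two_sample_ttest(a, b, equal_var=equal_var)
            rows.append(
                {
                    "feature": FEATURE_NAMES[col],
                    "rate_d": rate_d,
                    f"{pos}_mean": a.mean(),
                    f"{pos}_sd": a.std(ddof=1),
                    f"{neg}_mean": b.mean(),
                    f"{neg}_sd": b.std(ddof=1),
                    "t_statistic": t,
                    "p_value": p,
                }
            )
    table = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests

        table["p_holm"] = multipletests(table["p_value"], method="holm")[1]
    return table


def format_report(table: pd.DataFrame) -> str:
    """Plain-text 'mean +- SD (p)' report of a comparison table."""
    mean_cols = [c for c in table.columns if c.endswith("_mean")]
    lines = []
    for _, row in table.iterrows():
        cells = [
            f"{c[:-5]}: {row[c]:.4g} +- {row[c[:-5] + '_sd']:.4g}" for c in mean_cols
        ]
        lines.append(
            f"{row['feature']} (d={row['rate_d']}): "
            + "; ".join(cells)
            + f" (p = {row['p_value']:.4g})"
        )
    return "\n".join(lines)
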