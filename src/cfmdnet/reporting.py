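"""Small descriptive-reporting utilities (cohort tables, percentages)."""

from __future__ import annotations

import pandas as pd


def percentage(part: float, total: float, decimals: int = 1) -> float:
    """Share of ``part`` in ``total`` as a percentage rounded for reporting."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * part / total, decimals)


def category_table(covariates: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per category of every categorical covariate."""
    rows = []
    n = len(covariates)
    for col in covariates.columns:
        counts = covariates[col].value_counts(sort=False)
        for cat, cnt in counts.items():
            rows.append(
                {
                    "covariate": col,
                    "category": cat,
                    "n": int(cnt),
                    "percent": percentage(int(cnt), n),
                }
            )
    return pd.DataFrame(rows)
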