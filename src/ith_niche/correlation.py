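"""Cross-marker Spearman correlation over aligned grid squares.

Adjacent sections are aligned square-for-square, so each tumour square
yields one row of five marker values; pairwise Spearman rank correlations
are computed over all squares pooled within a prognostic subgroup, and
labelled by the conventional degree scheme (|rho| 0–0.2 none, 0.2–0.4
weak, 0.4–0.7 moderate-to-good, 0.7–1.0 good-to-very-good).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import TumourPanel

__all__ = [
    "CorrelationTable",
    "align_panels",
    "spearman_matrix",
    "degree_label",
    "DEGREE_BOUNDS",
]

#: |rho| lower bounds of the degree classes; boundary values go to the upper class
DEGREE_BOUNDS = ((0.7, "good-to-very-good"), (0.4, "moderate-to-good"), (0.2, "weak"), (0.0, "none"))


@dataclass
class CorrelationTable:
    """Pairwise Spearman correlations of one subgroup."""

    subgroup: str
    rho: pd.DataFrame  # markers × markers
    n: int  # squares used (listwise-complete rows)
    degrees: pd.DataFrame  # degree label per pair (off-diagonal)


def align_panels(panel: TumourPanel) -> pd.DataFrame:
    """One row per tumour square, columns = marker values.

    Requires all grids to share the lattice (enforced by TumourPanel).
    Squares with a missing value in any marker are dropped listwise.
    """
    if not panel.grids:
        raise ValueError("empty panel")
    ref = panel.reference_grid()
    mask = ref.tumour_mask
    data = {m: g.values[mask] for m, g in panel.grids.items()}
    df = pd.DataFrame(data)
    df.insert(0, "tumour", panel.tumour_id)
    return df.dropna()


def spearman_matrix(
    rows: pd.DataFrame, subgroup: str = "", min_rows: int = 10
) -> CorrelationTable:
    """Pairwise Spearman rho (average-rank ties) over pooled squares.

    A constant column has undefined correlation with every other column;
    those entries are reported as NaN.
    """
    value_cols = [c for c in rows.columns if c != "tumour"]
    df = rows[value_cols].dropna()
    if len(df) < min_rows:
        raise ValueError(f"need >= {min_rows} complete rows, got {len(df)}")
    markers = list(df.columns)
    k = len(markers)
    rho = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = df.iloc[:, i], df.iloc[:, j]
            if xi.nunique() < 2 or xj.nunique() < 2:
                r = np.nan
            else:
                r = stats.spearmanr(xi, xj).statistic
            rho[i, j] = rho[j, i] = r
    rho_df = pd.DataFrame(rho, index=markers, columns=markers)
    degrees = rho_df.map(lambda r: degree_label(r)[0] if np.isfinite(r) else "undefined")
    return CorrelationTable(subgroup=subgroup, rho=rho_df, n=len(df), degrees=degrees)


def degree_label(rho: float) -> tuple[str, str]:
    """Label a correlation coefficient's degree and sign.

    The degree is by |rho| (a strong negative correlation is still
    "moderate-to-good"); the sign is reported separately.
    """
    if not np.isfinite(rho) or abs(rho) > 1:
        raise ValueError(f"invalid correlation coefficient {rho!r}")
    a = abs(rho)
    for bound, name in DEGREE_BOUNDS:
        if a >= bound:
            sign = "negative" if rho < 0 else "positive"
            return name, sign
    raise AssertionError("unreachable")


def per_tumour_spearman(rows: pd.DataFrame, min_rows: int = 10) -> pd.DataFrame:
    """Alternative to pooling: Spearman matrices per tumour, averaged.

    Returns the element-wise mean rho across tumours with enough squares.
    """
    mats = []
    for _, sub in rows.groupby("tumour"):
        try:
            mats.append(spearman_matrix(sub, min_rows=min_rows).rho)
        except ValueError:
            continue
    if not mats:
        raise ValueError("no tumour had enough complete squares")
    return sum(mats) / len(mats)
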