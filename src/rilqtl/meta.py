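"""Meta-analysis of per-QTL interaction P-values.

Combines genome-wide interaction P-values across traits and crosses with
Fisher's combined probability test, and reports how many of the lowest
P-values would have to be dropped for the remaining median to reach 0.5
(a diagnostic for a weak excess of small P-values that Fisher's test
might miss).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class FisherResult:
    statistic: float  # X = -2 * sum(ln p)
    df: int
    p: float
    k: int


def fisher_combined(pvalues, n_perm: int = 10_000) -> FisherResult:
    """Fisher's combined probability test.

    X = -2 * sum(ln p) ~ chi-square with 2k df under the global null.
    Permutation P-values of exactly 0 (observation more extreme than every
    permutation) are replaced by 1/(2*n_perm) with a warning, since ln 0
    is undefined.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one P-value")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("P-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn(
            f"replacing {int((p == 0).sum())} zero P-value(s) with 1/(2*{n_perm})",
            stacklevel=2,
        )
        p = np.where(p == 0, 1.0 / (2.0 * n_perm), p)
    x = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return FisherResult(statistic=x, df=df, p=float(stats.chi2.sf(x, df)), k=p.size)


@dataclass(frozen=True)
class MedianRemoval:
    m: int  # smallest number of lowest P-values removed
    achieved: bool  # whether the target median was reached
    trajectory: tuple  # median after removing the m lowest, for every m


def median_removal_count(pvalues, target: float = 0.5) -> MedianRemoval:
    """How many of the lowest P-values must go for the median to reach target.

    Returns the smallest m such that median(all but the m lowest) >=
    target, plus the full median trajectory for m = 0 .. k-1. If even the
    single largest value falls short, m = k - 1 with ``achieved=False``.
    """
    p = np.sort(np.asarray(list(pvalues), dtype=float))
    if p.size == 0:
        raise ValueError("need at least one P-value")
    trajectory = tuple(float(np.median(p[m:])) for m in range(p.size))
    for m, med in enumerate(trajectory):
        if med >= target:
            return MedianRemoval(m=m, achieved=True, trajectory=trajectory)
    return MedianRemoval(m=p.size - 1, achieved=False, trajectory=trajectory)


def select_nonoverlapping(meta_input: pd.DataFrame) -> pd.DataFrame:
    """Keep one representative per overlap group of correlated QTLs.

    ``meta_input`` has columns ``qtl_id``, ``p`` and optionally ``group``
    (overlap group label; NaN/empty = independent) and ``lod``. Within a
    group only the member with the highest LOD enters the meta-analysis.
    """
    df = meta_input.copy()
    if "group" not in df.columns or df["group"].isna().all():
        return df
    keep = []
    for grp, rows in df.groupby(df["group"].fillna(df["qtl_id"].astype(str)), sort=False):
        if len(rows) == 1 or "lod" not in df.columns:
            keep.append(rows.iloc[[0]] if len(rows) == 1 else rows)
        else:
            keep.append(rows.loc[[rows["lod"].idxmax()]])
    return pd.concat(keep).sort_index()
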