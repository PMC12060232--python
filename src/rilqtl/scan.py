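"""Additive single-locus genome scan with permutation significance.

Per window, a Gaussian linear model y = b0 + b*g is fit by least squares
against the intercept-only model; the LOD score is
(n/2) * log10(RSS_null / RSS_model), the maximum-likelihood likelihood
ratio under Gaussian errors (single-marker Haley-Knott-style regression).
Genome-wide significance comes from the distribution of the maximum LOD
over phenotype permutations; peaks are called with LOD-drop support
intervals and minimum genetic separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AncestryMatrix, NullDistribution, validate_window_map
from .windows import retained_mask

#: Relative tolerance below which a model RSS counts as a perfect fit and
#: below which genotype variance counts as degenerate.
_EPS = 1e-12


def _as_phenotype(matrix: AncestryMatrix, phenotype) -> np.ndarray:
    if isinstance(phenotype, pd.Series):
        return phenotype.reindex(matrix.rils).to_numpy(dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if y.shape != (matrix.n_rils,):
        raise ValueError("phenotype length does not match number of RILs")
    return y


def _additive_stats(G: np.ndarray, y: np.ndarray):
    """Complete-case per-window OLS sufficient statistics.

    Returns ``(n, b, lod, degenerate, perfect)`` arrays over windows of
    ``G`` (RILs x windows, NaN = missing). Rows with missing phenotype are
    dropped globally; rows missing a genotype are dropped for that window
    only.
    """
    ok = ~np.isnan(y)
    G = G[ok]
    y = y[ok]
    y = y - y.mean() if y.size else y  # improves conditioning only
    M = ~np.isnan(G)
    Gm = np.where(M, G, 0.0)
    Mf = M.astype(float)
    n = Mf.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Sy = Mf.T @ y
        Syy = Mf.T @ (y * y)
        Sg = Gm.sum(axis=0)
        Sgg = (Gm * Gm).sum(axis=0)
        Sgy = Gm.T @ y
        sxx = Sgg - Sg * Sg / n
        sxy = Sgy - Sg * Sy / n
        rss0 = Syy - Sy * Sy / n
        b = sxy / sxx
        rss1 = rss0 - b * sxy
    degenerate = (n < 3) | (sxx <= _EPS * np.maximum(Sgg, 1.0))
    rss1 = np.clip(rss1, 0.0, None)
    perfect = (~degenerate) & (rss1 <= _EPS * np.maximum(rss0, _EPS)) & (rss0 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lod = (n / 2.0) * np.log10(rss0 / rss1)
    lod = np.where(degenerate, 0.0, lod)
    lod = np.where(perfect, np.inf, lod)
    lod = np.where((rss0 <= _EPS) & ~degenerate, 0.0, lod)  # constant phenotype
    lod = np.clip(lod, 0.0, None)
    b = np.where(degenerate, np.nan, b)
    return n.astype(int), b, lod, degenerate, perfect


def scan_additive(
    matrix: AncestryMatrix, phenotype, summary: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Single-marker additive LOD scan over all non-excluded windows.

    Returns a table with columns window_id, n, b, lod, excluded,
    degenerate, perfect_fit and an empty ``p`` column to be filled by
    :func:`genomewide_p`. Excluded (ancestry-skewed or all-missing)
    windows carry NaN LOD.
    """
    y = _as_phenotype(matrix, phenotype)
    keep = retained_mask(matrix, summary)
    n, b, lod, degen, perfect = _additive_stats(matrix.dosage, y)
    out = pd.DataFrame(
        {
            "window_id": matrix.windows,
            "n": n,
            "b": b,
            "lod": lod,
            "p": np.nan,
            "excluded": ~keep,
            "degenerate": degen,
            "perfect_fit": perfect,
        }
    )
    out.loc[~keep, ["b", "lod"]] = np.nan
    return out


def permutation_null(
    matrix: AncestryMatrix,
    phenotype,
    summary: pd.DataFrame | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    batch_size: int = 256,
) -> NullDistribution:
    """Genome-wide max-LOD null from phenotype permutations.

    Each permutation shuffles trait values jointly against whole genotype
    rows (preserving LD) and records the maximum LOD over non-excluded
    windows.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = _as_phenotype(matrix, phenotype)
    ok = ~np.isnan(y)
    yv = y[ok]
    yv = yv - yv.mean()
    G = matrix.dosage[ok][:, retained_mask(matrix, summary)]
    M = ~np.isnan(G)
    Gm = np.where(M, G, 0.0)
    Mf = M.astype(float)
    n = Mf.sum(axis=0)
    Sg = Gm.sum(axis=0)
    Sgg = (Gm * Gm).sum(axis=0)
    sxx = Sgg - Sg * Sg / n
    usable = (n >= 3) & (sxx > _EPS * np.maximum(Sgg, 1.0))

    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        Y = np.empty((yv.size, b))
        for k in range(b):
            Y[:, k] = rng.permutation(yv)
        with np.errstate(invalid="ignore", divide="ignore"):
            Sy = Mf.T @ Y
            Syy = Mf.T @ (Y * Y)
            Sgy = Gm.T @ Y
            sxy = Sgy - Sg[:, None] * Sy / n[:, None]
            rss0 = Syy - Sy * Sy / n[:, None]
            rss1 = np.clip(rss0 - sxy * sxy / sxx[:, None], _EPS * rss0, None)
            lod = (n[:, None] / 2.0) * np.log10(rss0 / rss1)
        lod[~usable] = 0.0
        maxima[done : done + b] = np.nanmax(np.clip(lod, 0.0, None), axis=0)
        done += b
    return NullDistribution(maxima, n_perm=n_perm, seed=seed, statistic="max_lod")


def genomewide_p(scan: pd.DataFrame, null: NullDistribution, plus_one: bool = False) -> pd.DataFrame:
    """Attach genome-wide empirical P-values to a scan table.

    P(window) = proportion of null maxima >= the window's LOD; 0 means the
    LOD exceeded every permutation maximum.
    """
    out = scan.copy()
    lod = out["lod"].to_numpy(dtype=float)
    p = np.full(lod.size, np.nan)
    finite = ~np.isnan(lod)
    p[finite] = null.p_value(lod[finite], plus_one=plus_one)
    out["p"] = p
    return out


def qtl_h2(lod: float, n: int) -> float:
    """QTL heritability from LOD: h2 = 1 - 10^(-2*LOD/n).

    Equals the regression R^2 of the same single-window fit.
    """
    if lod < 0:
        raise ValueError("lod must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1.0 - 10.0 ** (-2.0 * lod / n)


@dataclass(frozen=True)
class QTLCall:
    """A called QTL peak with its LOD-drop support interval."""

    peak_window: object
    arm: str
    lod: float
    p: float
    b: float
    n: int
    h2: float
    cM: float
    ci_windows: tuple
    ci_start: int
    ci_end: int

    def to_dict(self) -> dict:
        d = {
            "peak_window": self.peak_window,
            "arm": self.arm,
            "lod": self.lod,
            "p": self.p,
            "b": self.b,
            "n": int(self.n),
            "h2": self.h2,
            "cM": self.cM,
            "ci_first": self.ci_windows[0],
            "ci_last": self.ci_windows[-1],
            "ci_start": int(self.ci_start),
            "ci_end": int(self.ci_end),
        }
        return d


def _local_peak_indices(lod: np.ndarray) -> list:
    """Indices of strict local maxima; a plateau is represented by its
    first index."""
    peaks = []
    k = len(lod)
    i = 0
    while i < k:
        j = i
        while j + 1 < k and lod[j + 1] == lod[i]:
            j += 1
        left_ok = i == 0 or lod[i - 1] < lod[i]
        right_ok = j == k - 1 or lod[j + 1] < lod[i]
        if left_ok and right_ok:
            peaks.append(i)
        i = j + 1
    return peaks


def call_qtl_peaks(
    scan: pd.DataFrame,
    wmap: pd.DataFrame,
    alpha: float = 0.10,
    lod_drop: float = 1.5,
    min_sep_cM: float = 10.0,
) -> list:
    """Call QTL peaks from a P-value-annotated scan.

    Rules, applied per arm over non-excluded windows in map order:

    1. putative QTLs are windows with genome-wide P strictly below alpha;
    2. putative peaks are putative QTLs that are local LOD maxima;
    3. for every pair of peaks, if no intervening window's LOD falls below
       (minor peak LOD - lod_drop), the minor peak is removed (pairs
       processed by descending minor LOD, re-evaluated after each removal);
    4. any peak closer than ``min_sep_cM`` (genetic midpoints) to a
       higher-LOD peak is removed;
    5. the support interval is the maximal contiguous run of windows with
       LOD > peak LOD - lod_drop containing the peak.

    Excluded windows are transparent: contiguity and "intervening" are
    evaluated over the retained windows of the arm.
    """
    if scan["p"].isna().all():
        raise ValueError("scan has no P-values; run genomewide_p first")
    wmap = validate_window_map(wmap)
    merged = wmap.merge(scan, on="window_id", how="inner")
    calls = []
    for arm, grp in merged.groupby("arm", sort=False):
        grp = grp[~grp["excluded"]].reset_index(drop=True)
        if grp.empty:
            continue
        lod = grp["lod"].to_numpy(dtype=float)
        p = grp["p"].to_numpy(dtype=float)
        putative = p < alpha
        peaks = [i for i in _local_peak_indices(lod) if putative[i]]

        # Rule 3: prune peak pairs lacking a deep-enough valley.
        changed = True
        while changed and len(peaks) > 1:
            changed = False
            pairs = sorted(
                ((i, j) for i in peaks for j in peaks if i < j),
                key=lambda ij: -min(lod[ij[0]], lod[ij[1]]),
            )
            for i, j in pairs:
                between = lod[i + 1 : j]
                minor = i if lod[i] <= lod[j] else j
                if between.size == 0 or not (between < lod[minor] - lod_drop).any():
                    peaks.remove(minor)
                    changed = True
                    break

        # Rule 4: minimum genetic separation, favoring higher LOD.
        cm = grp["cM"].to_numpy(dtype=float)
        kept = []
        for i in sorted(peaks, key=lambda i: (-lod[i], cm[i])):
            if all(abs(cm[i] - cm[j]) >= min_sep_cM for j in kept):
                kept.append(i)

        for i in sorted(kept):
            lo = i
            while lo - 1 >= 0 and lod[lo - 1] > lod[i] - lod_drop:
                lo -= 1
            hi = i
            while hi + 1 < len(lod) and lod[hi + 1] > lod[i] - lod_drop:
                hi += 1
            ci = grp.loc[lo:hi]
            calls.append(
                QTLCall(
                    peak_window=grp.loc[i, "window_id"],
                    arm=arm,
                    lod=float(lod[i]),
                    p=float(p[i]),
                    b=float(grp.loc[i, "b"]),
                    n=int(grp.loc[i, "n"]),
                    h2=qtl_h2(min(float(lod[i]), 1e6), int(grp.loc[i, "n"])),
                    cM=float(cm[i]),
                    ci_windows=tuple(ci["window_id"]),
                    ci_start=int(ci["start"].min()),
                    ci_end=int(ci["end"].max()),
                )
            )
    calls.sort(key=lambda c: -c.lod)
    return calls


def correlate_traits(phenotypes: pd.DataFrame):
    """Pairwise Pearson correlations on pairwise-complete observations.

    Returns ``(r, p, n)`` DataFrames indexed by trait. Pairs with fewer
    than 3 complete observations are left NaN.
    """
    traits = list(phenotypes.columns)
    k = len(traits)
    r = np.full((k, k), np.nan)
    pv = np.full((k, k), np.nan)
    nn = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            a = phenotypes[traits[i]].to_numpy(dtype=float)
            b = phenotypes[traits[j]].to_numpy(dtype=float)
            ok = ~np.isnan(a) & ~np.isnan(b)
            nn[i, j] = nn[j, i] = ok.sum()
            if ok.sum() < 3:
                continue
            res = stats.pearsonr(a[ok], b[ok])
            r[i, j] = r[j, i] = res.statistic
            pv[i, j] = pv[j, i] = res.pvalue
    idx = pd.Index(traits)
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(pv, index=idx, columns=idx),
        pd.DataFrame(nn, index=idx, columns=idx),
    )


def map_residuals(
    traitA, traitB, matrix: AncestryMatrix, summary: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Scan the residuals of traitA regressed on traitB.

    Used for correlated trait pairs sharing a QTL: the residual scan asks
    whether traitA carries signal beyond its correlation with traitB. RILs
    incomplete for either trait get NaN residuals (dropped in the scan).
    """
    a = _as_phenotype(matrix, traitA)
    b = _as_phenotype(matrix, traitB)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        raise ValueError("need >= 3 complete trait pairs")
    if np.ptp(b[ok]) == 0:
        raise ValueError("traitB is constant; residuals undefined")
    slope, intercept = np.polyfit(b[ok], a[ok], 1)
    resid = np.full(a.size, np.nan)
    resid[ok] = a[ok] - (intercept + slope * b[ok])
    return scan_additive(matrix, resid, summary)
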