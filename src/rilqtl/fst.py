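"""Window-level F_ST statistics and per-arm outlier flagging.

Two window statistics are computed from biallelic SNPs: the window-wide
F_ST (Hudson-type ratio of summed numerator and denominator components
across the window's SNPs) and the maximum single-SNP F_ST in the window.
Outliers are the top fraction (default 1%) of windows per chromosome arm
for either statistic — or for an optional user-supplied third statistic —
restricted to high-recombination regions where selection signals are
expected to be localized.

The Hudson estimator is used throughout (a deliberate convention choice;
other F_ST conventions differ in weighting):

    numerator   = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    denominator = p1(1-p2) + p2(1-p1)
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .core import validate_window_map

logger = logging.getLogger(__name__)

#: Default high-recombination intervals (bp, 0-based half-open) per arm:
#: regions with recombination rates generally above 0.5 cM/Mb in the
#: D. melanogaster map.
DEFAULT_HIGH_RECOMB = {
    "X": [(2_300_000, 21_400_000)],
    "2L": [(500_000, 17_500_000)],
    "2R": [(5_200_000, 20_800_000)],
    "3L": [(600_000, 17_700_000)],
    "3R": [(6_900_000, 26_600_000)],
}


def snp_fst(ac1, n1, ac2, n2):
    """Hudson F_ST components per SNP.

    Parameters are derived-allele counts and sampled allele (chromosome)
    counts per population; each may be a scalar or array. Returns
    ``(numerator, denominator)``; SNPs monomorphic in both populations get
    (0, 0) and are excluded from ratio-of-sums by contributing nothing.
    """
    ac1 = np.asarray(ac1, dtype=float)
    ac2 = np.asarray(ac2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("each population needs >= 2 sampled alleles")
    p1 = ac1 / n1
    p2 = ac2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    mono = den == 0
    return np.where(mono, 0.0, num), np.where(mono, 0.0, den)


def window_fst_from_arrays(arm, pos, ac1, n1, ac2, n2, wmap: pd.DataFrame) -> pd.DataFrame:
    """Window F_ST from per-SNP arrays (arm label, position, counts).

    Returns one row per map window: ``fst_fullwin`` (ratio of sums),
    ``fst_maxsnp`` (max per-SNP ratio among SNPs with positive
    denominator, clipped to [0,1] for reporting; raw values retained in
    ``fst_maxsnp_raw``/``fst_fullwin_raw``) and ``n_snps_used``. Windows
    with no usable SNP are NaN.
    """
    wmap = validate_window_map(wmap)
    arm = np.asarray(arm, dtype=object)
    pos = np.asarray(pos)
    num, den = snp_fst(ac1, n1, ac2, n2)
    rows = []
    for _, w in wmap.iterrows():
        sel = (arm == w["arm"]) & (pos >= w["start"]) & (pos < w["end"])
        nsel = num[sel]
        dsel = den[sel]
        usable = dsel > 0
        if usable.sum() == 0:
            rows.append(
                {
                    "window_id": w["window_id"],
                    "arm": w["arm"],
                    "fst_fullwin_raw": np.nan,
                    "fst_maxsnp_raw": np.nan,
                    "n_snps_used": 0,
                }
            )
            continue
        full = nsel[usable].sum() / dsel[usable].sum()
        maxsnp = (nsel[usable] / dsel[usable]).max()
        rows.append(
            {
                "window_id": w["window_id"],
                "arm": w["arm"],
                "fst_fullwin_raw": full,
                "fst_maxsnp_raw": maxsnp,
                "n_snps_used": int(usable.sum()),
            }
        )
    out = pd.DataFrame(rows)
    out["fst_fullwin"] = out["fst_fullwin_raw"].clip(0.0, 1.0)
    out["fst_maxsnp"] = out["fst_maxsnp_raw"].clip(0.0, 1.0)
    return out.merge(wmap[["window_id", "start", "end"]], on="window_id")


def window_fst_from_genotypes(genotypes, labels, arm, pos, wmap, pops=("pop1", "pop2")):
    """Window F_ST from a samples-by-SNPs diploid 0/1/2 genotype matrix."""
    genotypes = np.asarray(genotypes, dtype=float)
    labels = np.asarray(labels, dtype=object)
    parts = []
    for pop in pops:
        g = genotypes[labels == pop]
        called = ~np.isnan(g)
        parts.append((np.nansum(g, axis=0), 2.0 * called.sum(axis=0)))
    (ac1, n1), (ac2, n2) = parts
    return window_fst_from_arrays(arm, pos, ac1, n1, ac2, n2, wmap)


def window_fst_vcf(vcf_path, wmap: pd.DataFrame, pop_assignments: pd.DataFrame, pops=None):
    """Window F_ST from a VCF plus a (sample, population) assignment table.

    Only biallelic SNPs are used; others are skipped with a logged count.
    ``pop_assignments`` has columns ``sample`` and ``population`` naming
    exactly two populations (or pass ``pops`` to pick two).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    assign = dict(zip(pop_assignments["sample"], pop_assignments["population"]))
    if pops is None:
        pops = sorted(set(assign.values()))
    if len(pops) != 2:
        raise ValueError(f"need exactly two populations, got {pops}")
    sample_pops = np.array([assign.get(s) for s in vcf.samples], dtype=object)
    idx1 = np.nonzero(sample_pops == pops[0])[0]
    idx2 = np.nonzero(sample_pops == pops[1])[0]
    arms, positions, ac1s, n1s, ac2s, n2s = [], [], [], [], [], []
    skipped = 0
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            skipped += 1
            continue
        g = np.asarray(var.genotype.array(), dtype=float)[:, :2]
        g[g < 0] = np.nan
        dose = g.sum(axis=1)
        for idx, acs, ns in ((idx1, ac1s, n1s), (idx2, ac2s, n2s)):
            sub = dose[idx]
            called = ~np.isnan(sub)
            acs.append(np.nansum(sub))
            ns.append(2.0 * called.sum())
        arms.append(var.CHROM)
        positions.append(var.POS - 1)  # VCF is 1-based; map is 0-based
    if skipped:
        logger.info("skipped %d non-biallelic-SNP records", skipped)
    ok = (np.asarray(n1s) >= 2) & (np.asarray(n2s) >= 2)
    return window_fst_from_arrays(
        np.asarray(arms, dtype=object)[ok],
        np.asarray(positions)[ok],
        np.asarray(ac1s)[ok],
        np.asarray(n1s)[ok],
        np.asarray(ac2s)[ok],
        np.asarray(n2s)[ok],
        wmap,
    )


def flag_outliers(
    results: pd.DataFrame,
    top_fraction: float = 0.01,
    recomb_intervals: dict | None = None,
    extra_statistics=(),
) -> pd.DataFrame:
    """Flag per-arm top-fraction outlier windows for any statistic.

    Eligibility requires the window midpoint to fall inside a
    high-recombination interval of its arm (default: the shipped
    D. melanogaster intervals). Per arm and statistic, the top
    ``top_fraction`` of eligible windows are flagged, ties at the
    threshold included; arms with fewer than 1/top_fraction eligible
    windows flag at least the single maximum (with a warning). A window is
    an outlier if flagged for any statistic; additional pre-computed
    statistic columns (e.g. a haplotype statistic) can be included via
    ``extra_statistics``.
    """
    if recomb_intervals is None:
        recomb_intervals = DEFAULT_HIGH_RECOMB
    stats_cols = ["fst_fullwin", "fst_maxsnp", *extra_statistics]
    out = results.copy()
    mid = (out["start"] + out["end"]) / 2.0
    eligible = np.zeros(len(out), dtype=bool)
    for arm, intervals in recomb_intervals.items():
        sel = out["arm"] == arm
        for lo, hi in intervals:
            eligible |= sel & (mid >= lo) & (mid < hi)
    out["eligible"] = eligible
    for col in stats_cols:
        out[f"outlier_{col}"] = False
    for arm, grp in out.groupby("arm", sort=False):
        elig = grp[grp["eligible"]]
        for col in stats_cols:
            vals = elig[col].dropna()
            if vals.empty:
                continue
            k = int(np.floor(top_fraction * len(vals)))
            if k < 1:
                warnings.warn(
                    f"arm {arm}: fewer than {int(1/top_fraction)} eligible windows; "
                    "flagging the single maximum",
                    stacklevel=2,
                )
                k = 1
            threshold = np.sort(vals.to_numpy())[-k]
            flag_idx = elig.index[elig[col] >= threshold]
            out.loc[flag_idx, f"outlier_{col}"] = True
    out["outlier"] = out[[f"outlier_{c}" for c in stats_cols]].any(axis=1)
    return out
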