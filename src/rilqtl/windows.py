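"""Window-level genotype construction and filters.

Converts per-SNP diploid ancestry calls into the window dosage matrix
(majority call per window), merges adjacent windows that are identical
across all RILs, and flags windows with extreme ancestry skew for
exclusion from the scans.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import AncestryMatrix, validate_window_map

logger = logging.getLogger(__name__)


def summarize_windows(per_snp_calls: pd.DataFrame, wmap: pd.DataFrame) -> AncestryMatrix:
    """Collapse per-SNP ancestry calls to one majority call per window.

    Parameters
    ----------
    per_snp_calls
        Tidy table with columns ``ril``, ``arm``, ``pos`` (bp) and
        ``call`` (0/1/2 dosage or NaN for missing).
    wmap
        Window map; SNPs are assigned by ``[start, end)`` on their arm.

    A window's dosage for a RIL is the most frequent non-missing call among
    its SNPs; an exact tie is resolved toward the lower dosage (ancestral);
    a window with no covered, non-missing SNP is missing. SNPs falling
    outside every window are ignored (count logged).
    """
    wmap = validate_window_map(wmap)
    df = per_snp_calls.copy()
    required = {"ril", "arm", "pos", "call"}
    if not required.issubset(df.columns):
        raise ValueError(f"per-SNP call table needs columns {sorted(required)}")

    # Assign each SNP to a window via per-arm interval lookup.
    df["window_id"] = pd.NA
    for arm, grp in wmap.groupby("arm", sort=False):
        sel = df["arm"] == arm
        if not sel.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        ids = grp["window_id"].to_numpy(dtype=object)
        pos = df.loc[sel, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        assigned = np.full(pos.size, None, dtype=object)
        assigned[inside] = ids[idx[inside]]
        df.loc[sel, "window_id"] = assigned

    n_outside = int(df["window_id"].isna().sum())
    if n_outside:
        logger.info("%d SNP calls fall outside all windows; ignored", n_outside)
    df = df.dropna(subset=["window_id", "call"])

    counts = (
        df.groupby(["ril", "window_id", "call"], sort=False)
        .size()
        .rename("n")
        .reset_index()
    )
    # Majority with lower-dosage tie-break: sort by (count desc, call asc).
    counts = counts.sort_values(["n", "call"], ascending=[False, True], kind="stable")
    majority = counts.drop_duplicates(["ril", "window_id"], keep="first")

    rils = np.array(sorted(per_snp_calls["ril"].unique()), dtype=object)
    window_ids = wmap["window_id"].to_numpy(dtype=object)
    dosage = np.full((rils.size, window_ids.size), np.nan)
    ril_idx = {r: i for i, r in enumerate(rils)}
    win_idx = {w: j for j, w in enumerate(window_ids)}
    for r, w, c in majority[["ril", "window_id", "call"]].itertuples(index=False):
        dosage[ril_idx[r], win_idx[w]] = float(c)
    return AncestryMatrix(rils, window_ids, dosage)


def _columns_identical(a: np.ndarray, b: np.ndarray) -> bool:
    """Elementwise equality with NaN == NaN."""
    both_nan = np.isnan(a) & np.isnan(b)
    return bool(np.all(both_nan | (a == b)))


def merge_identical_adjacent(matrix: AncestryMatrix, wmap: pd.DataFrame):
    """Merge runs of adjacent same-arm windows identical across all RILs.

    The merged window keeps the first window's id, spans the union of the
    physical intervals, sums ``n_snps``, and takes its genetic position as
    the midpoint of the first and last members' cM values. Returns
    ``(matrix, window map)``; idempotent on its own output.
    """
    wmap = validate_window_map(wmap)
    order = {w: j for j, w in enumerate(matrix.windows)}
    rows = []
    keep_cols = []
    i = 0
    recs = wmap.to_dict("records")
    while i < len(recs):
        j = i
        ci = order[recs[i]["window_id"]]
        while (
            j + 1 < len(recs)
            and recs[j + 1]["arm"] == recs[i]["arm"]
            and _columns_identical(
                matrix.dosage[:, ci], matrix.dosage[:, order[recs[j + 1]["window_id"]]]
            )
        ):
            j += 1
        merged = dict(recs[i])
        merged["end"] = recs[j]["end"]
        merged["n_snps"] = sum(r["n_snps"] for r in recs[i : j + 1])
        merged["cM"] = (recs[i]["cM"] + recs[j]["cM"]) / 2.0
        rows.append(merged)
        keep_cols.append(ci)
        i = j + 1
    new_map = pd.DataFrame(rows)
    new_matrix = AncestryMatrix(
        matrix.rils, new_map["window_id"].to_numpy(dtype=object), matrix.dosage[:, keep_cols]
    )
    return new_matrix, new_map


def flag_skewed(matrix: AncestryMatrix, threshold: float = 0.9) -> pd.DataFrame:
    """Per-window ancestry summary with the skew-exclusion flag.

    ``derived_prop`` is mean(dosage)/2 over non-missing RILs (heterozygotes
    count as half). A window is excluded when derived_prop >= threshold or
    <= 1 - threshold ("90% or greater" bias toward either ancestry), or
    when it has no non-missing call (``all_missing``).
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    d = matrix.dosage
    obs = ~np.isnan(d)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        derived = np.where(obs, d, 0.0).sum(axis=0) / 2.0 / n_obs
        het = np.where(obs, d == 1.0, False).sum(axis=0) / n_obs
    all_missing = n_obs == 0
    derived = np.where(all_missing, np.nan, derived)
    het = np.where(all_missing, np.nan, het)
    with np.errstate(invalid="ignore"):
        excluded = all_missing | (derived >= threshold) | ((1.0 - derived) >= threshold)
    return pd.DataFrame(
        {
            "window_id": matrix.windows,
            "derived_prop": derived,
            "het_frac": het,
            "missing_frac": 1.0 - n_obs / matrix.n_rils,
            "all_missing": all_missing,
            "skew_excluded": excluded,
        }
    )


def retained_mask(matrix: AncestryMatrix, summary: pd.DataFrame | None) -> np.ndarray:
    """Boolean mask over matrix windows of scan-eligible (non-excluded) windows."""
    if summary is None:
        return np.ones(matrix.n_windows, dtype=bool)
    excl = dict(zip(summary["window_id"], summary["skew_excluded"]))
    return np.array([not excl.get(w, False) for w in matrix.windows], dtype=bool)
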