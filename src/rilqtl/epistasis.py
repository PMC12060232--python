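"""Two-locus epistasis scan with a focal-fixed permutation null.

For a focal QTL window, every eligible partner window is tested with the
likelihood ratio of ``y ~ g1 + g2 + g1:g2`` against ``y ~ g1 + g2``, both
fit by least squares with numeric dosages (the interaction is the single
product term, one degree of freedom):

    interaction LOD = (n/2) * log10(RSS_additive / RSS_full)

Partners exclude the focal QTL's support interval and skew-excluded
windows. The null fixes the focal window, shuffles the phenotype, rescans
all partners, and keeps the genome-wide maximum interaction LOD; observed
maxima are scored as the proportion of null maxima at least as large.
This null destroys the focal main effect as well, which makes it
conservative when that main effect is strong.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AncestryMatrix, NullDistribution
from .windows import retained_mask

_EPS = 1e-12


def _pair_rss(y: np.ndarray, g1: np.ndarray, g2: np.ndarray):
    """(RSS_additive, RSS_full, df-usable flag) by QR least squares."""
    n = y.size
    ones = np.ones(n)
    Xa = np.column_stack([ones, g1, g2])
    Xf = np.column_stack([ones, g1, g2, g1 * g2])
    _, rss_a, rank_a, _ = np.linalg.lstsq(Xa, y, rcond=None)
    _, rss_f, rank_f, _ = np.linalg.lstsq(Xf, y, rcond=None)

    def _rss(X, res, rank):
        if res.size:
            return float(res[0])
        fit = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(np.sum((y - fit) ** 2))

    return _rss(Xa, rss_a, rank_a), _rss(Xf, rss_f, rank_f), rank_f > rank_a


def interaction_lod(matrix: AncestryMatrix, phenotype, w1, w2) -> float:
    """Interaction LOD between two windows (complete-case at both).

    Returns 0 when the product term is collinear with the additive model
    (degenerate design, e.g. no RIL carries derived alleles at both loci);
    +inf when the full model fits perfectly. Symmetric in (w1, w2) by
    construction: windows are ordered canonically before fitting.
    """
    if w1 == w2:
        raise ValueError("w1 and w2 must differ")
    i1, i2 = matrix.window_index(w1), matrix.window_index(w2)
    if i2 < i1:  # canonical order => exact symmetry
        i1, i2 = i2, i1
    y = np.asarray(phenotype, dtype=float)
    g1 = matrix.dosage[:, i1]
    g2 = matrix.dosage[:, i2]
    ok = ~np.isnan(y) & ~np.isnan(g1) & ~np.isnan(g2)
    if ok.sum() < 4:
        raise ValueError("need >= 4 RILs complete at both windows")
    y, g1, g2 = y[ok], g1[ok], g2[ok]
    y = y - y.mean()
    rss_a, rss_f, usable = _pair_rss(y, g1, g2)
    if not usable or rss_a <= _EPS * max(np.sum(y * y), _EPS):
        return 0.0
    if rss_f <= _EPS * rss_a:
        return np.inf
    return max(0.0, (y.size / 2.0) * np.log10(rss_a / rss_f))


class InteractionScanner:
    """Precomputed fixed-focal interaction scan over many phenotypes.

    Builds, once per (panel, focal window, partner set), the per-partner
    Gram matrices of the additive and full designs and their
    pseudo-inverses; each subsequent phenotype costs two tall-matrix
    contractions. Requires complete genotypes (no missing calls) across the
    focal and partner windows; RILs missing the focal call are dropped.
    """

    def __init__(
        self,
        matrix: AncestryMatrix,
        focal_window,
        partner_ids=None,
        summary: pd.DataFrame | None = None,
        exclude_windows=(),
    ):
        self.focal_window = focal_window
        fi = matrix.window_index(focal_window)
        keep = retained_mask(matrix, summary)
        excl = set(exclude_windows) | {focal_window}
        if partner_ids is None:
            partner_ids = [
                w for w, k in zip(matrix.windows, keep) if k and w not in excl
            ]
        else:
            partner_ids = [w for w in partner_ids if w not in excl]
        if not partner_ids:
            raise ValueError("no eligible partner windows")
        self.partner_ids = np.asarray(partner_ids, dtype=object)
        cols = [matrix.window_index(w) for w in partner_ids]

        g1 = matrix.dosage[:, fi]
        self._row_ok = ~np.isnan(g1)
        g1 = g1[self._row_ok]
        G = matrix.dosage[self._row_ok][:, cols]
        if np.isnan(G).any():
            raise ValueError(
                "InteractionScanner requires complete partner genotypes; "
                "use interaction_lod per pair for matrices with missing calls"
            )
        n, w = G.shape
        self.n = n
        ones = np.ones(n)
        P = g1[:, None] * G
        # Stacked designs: X[w] = [1, g1, g2_w, g1*g2_w], shape (w, n, 4).
        X = np.empty((w, n, 4))
        X[:, :, 0] = ones
        X[:, :, 1] = g1
        X[:, :, 2] = G.T
        X[:, :, 3] = P.T
        self._X = X
        A_full = np.einsum("wni,wnj->wij", X, X, optimize=True)
        A_add = A_full[:, :3, :3]
        self._Ainv_full = np.linalg.pinv(A_full, hermitian=True)
        self._Ainv_add = np.linalg.pinv(A_add, hermitian=True)
        rank_full = np.linalg.matrix_rank(A_full, hermitian=True)
        rank_add = np.linalg.matrix_rank(A_add, hermitian=True)
        self.degenerate = rank_full <= rank_add

    def lods(self, phenotype: np.ndarray) -> np.ndarray:
        """Interaction LOD against every partner for one phenotype vector
        (aligned to the panel's RILs)."""
        return self.lods_many(np.asarray(phenotype, dtype=float)[:, None])[:, 0]

    def lods_many(self, Y: np.ndarray) -> np.ndarray:
        """Interaction LODs for a batch of phenotypes.

        ``Y`` has one column per phenotype (rows aligned to the panel's
        RILs); returns an array of shape (n_partners, n_phenotypes).
        """
        Y = Y[self._row_ok]
        if np.isnan(Y).any():
            raise ValueError("missing phenotypes not supported in batch mode")
        Y = Y - Y.mean(axis=0, keepdims=True)
        yy = np.einsum("nb,nb->b", Y, Y)
        T = np.einsum("wni,nb->wib", self._X, Y, optimize=True)
        fit_full = np.einsum("wib,wij,wjb->wb", T, self._Ainv_full, T, optimize=True)
        fit_add = np.einsum(
            "wib,wij,wjb->wb", T[:, :3], self._Ainv_add, T[:, :3], optimize=True
        )
        rss_full = np.clip(yy[None, :] - fit_full, 0.0, None)
        rss_add = np.clip(yy[None, :] - fit_add, 0.0, None)
        with np.errstate(invalid="ignore", divide="ignore"):
            lod = (self.n / 2.0) * np.log10(
                rss_add / np.maximum(rss_full, _EPS * np.maximum(rss_add, _EPS))
            )
        lod[self.degenerate, :] = 0.0
        lod[rss_add <= _EPS * np.maximum(yy, _EPS)[None, :]] = 0.0
        return np.clip(np.nan_to_num(lod, nan=0.0), 0.0, None)

    def max_lods(self, Y: np.ndarray) -> np.ndarray:
        """Genome-wide maximum interaction LOD per phenotype column."""
        return self.lods_many(Y).max(axis=0)


@dataclass(frozen=True)
class InteractionScan:
    """Result of scanning one focal QTL against all eligible partners."""

    focal_window: object
    partner_ids: np.ndarray
    lods: np.ndarray
    max_lod: float
    max_partner: object
    p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"partner": self.partner_ids, "interaction_lod": self.lods}
        )


def interaction_scan(
    matrix: AncestryMatrix,
    phenotype,
    qtl,
    summary: pd.DataFrame | None = None,
) -> InteractionScan:
    """Scan a focal QTL against every window outside its support interval.

    ``qtl`` is a :class:`rilqtl.scan.QTLCall` (its ``ci_windows`` are
    excluded as partners) or a bare window id (no exclusion beyond the
    focal window itself).
    """
    focal, excluded = _focal_and_ci(qtl)
    y = np.asarray(phenotype, dtype=float)
    scanner = InteractionScanner(
        matrix, focal, summary=summary, exclude_windows=excluded
    )
    ok = ~np.isnan(y)
    if not ok.all():
        lods = np.array(
            [
                interaction_lod(matrix, np.where(ok, y, np.nan), focal, w)
                for w in scanner.partner_ids
            ]
        )
    else:
        lods = scanner.lods(y)
    imax = int(np.argmax(lods))
    return InteractionScan(
        focal_window=focal,
        partner_ids=scanner.partner_ids,
        lods=lods,
        max_lod=float(lods[imax]),
        max_partner=scanner.partner_ids[imax],
    )


def _focal_and_ci(qtl):
    if hasattr(qtl, "peak_window"):
        return qtl.peak_window, tuple(qtl.ci_windows)
    return qtl, ()


def interaction_null(
    matrix: AncestryMatrix,
    phenotype,
    qtl,
    summary: pd.DataFrame | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    batch_size: int = 256,
) -> NullDistribution:
    """Focal-fixed permutation null of the genome-wide max interaction LOD."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    focal, excluded = _focal_and_ci(qtl)
    y = np.asarray(phenotype, dtype=float)
    ok = ~np.isnan(y)
    yv = y[ok]
    sub = AncestryMatrix(matrix.rils[ok], matrix.windows, matrix.dosage[ok])
    scanner = InteractionScanner(sub, focal, summary=summary, exclude_windows=excluded)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        Y = np.empty((yv.size, b))
        for k in range(b):
            Y[:, k] = rng.permutation(yv)
        maxima[done : done + b] = scanner.max_lods(Y)
        done += b
    return NullDistribution(
        maxima, n_perm=n_perm, seed=seed, statistic="max_interaction_lod"
    )


def interaction_p(scan: InteractionScan, null: NullDistribution) -> float:
    """Genome-wide interaction P: share of null maxima >= the observed max."""
    return float(null.p_value(scan.max_lod))
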