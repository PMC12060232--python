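"""Shared containers for window-based RIL genotype data.

The pipeline's coordinate system is a :class:`WindowMap`-style table of
nonoverlapping genomic windows (chromosome arm, physical span, genetic
position, SNP count) and its genotype container is an
:class:`AncestryMatrix`: a RIL-by-window matrix of ancestry dosages, where
0 is the ancestral-population homozygote, 1 a heterozygote, 2 the
derived-population homozygote, and NaN missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of a window map table, in canonical order.
#: ``start``/``end`` are 0-based half-open physical coordinates in bp;
#: ``cM`` is the genetic midpoint of the window on its arm.
WINDOW_MAP_COLUMNS = ["window_id", "arm", "start", "end", "cM", "n_snps"]

DOSAGE_VALUES = (0.0, 1.0, 2.0)


class ConfigurationError(ValueError):
    """Raised for invalid simulator or pipeline configuration."""


@dataclass(frozen=True)
class AncestryMatrix:
    """RIL-by-window ancestry dosage matrix.

    Parameters
    ----------
    rils
        RIL identifiers, one per row.
    windows
        Window identifiers, one per column, aligned to a window map.
    dosage
        Float array of shape ``(n_rils, n_windows)`` with values in
        {0, 1, 2} or NaN for missing calls.
    """

    rils: np.ndarray
    windows: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        rils = np.asarray(self.rils, dtype=object)
        windows = np.asarray(self.windows, dtype=object)
        dosage = np.asarray(self.dosage, dtype=float)
        if dosage.ndim != 2 or dosage.shape != (rils.size, windows.size):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{rils.size} RILs x {windows.size} windows"
            )
        finite = dosage[~np.isnan(dosage)]
        if finite.size and not np.isin(finite, DOSAGE_VALUES).all():
            bad = np.unique(finite[~np.isin(finite, DOSAGE_VALUES)])
            raise ValueError(f"dosage values outside {{0,1,2,NA}}: {bad}")
        if len(set(windows.tolist())) != windows.size:
            raise ValueError("duplicate window ids")
        object.__setattr__(self, "rils", rils)
        object.__setattr__(self, "windows", windows)
        object.__setattr__(self, "dosage", dosage)

    @property
    def n_rils(self) -> int:
        return self.rils.size

    @property
    def n_windows(self) -> int:
        return self.windows.size

    def window_index(self, window_id) -> int:
        idx = np.nonzero(self.windows == window_id)[0]
        if idx.size == 0:
            raise KeyError(f"unknown window id: {window_id!r}")
        return int(idx[0])

    def column(self, window_id) -> np.ndarray:
        """Dosage vector at one window (length ``n_rils``)."""
        return self.dosage[:, self.window_index(window_id)]

    def subset_windows(self, window_ids) -> "AncestryMatrix":
        idx = [self.window_index(w) for w in window_ids]
        return AncestryMatrix(self.rils, self.windows[idx], self.dosage[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage, index=pd.Index(self.rils, name="ril"), columns=self.windows
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AncestryMatrix":
        return cls(
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
            df.to_numpy(dtype=float),
        )


def validate_window_map(wmap: pd.DataFrame) -> pd.DataFrame:
    """Validate a window map table and return it with canonical columns.

    Windows within an arm must be sorted, nonoverlapping (0-based
    half-open) and have nondecreasing genetic positions.
    """
    missing = [c for c in WINDOW_MAP_COLUMNS if c not in wmap.columns]
    if missing:
        raise ValueError(f"window map missing columns: {missing}")
    wmap = wmap[WINDOW_MAP_COLUMNS].copy()
    if wmap["window_id"].duplicated().any():
        raise ValueError("duplicate window ids in map")
    if (wmap["end"] <= wmap["start"]).any():
        raise ValueError("window end must exceed start")
    for arm, grp in wmap.groupby("arm", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cm = grp["cM"].to_numpy()
        if not (np.diff(starts) > 0).all():
            raise ValueError(f"arm {arm}: windows not sorted by start")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"arm {arm}: overlapping windows")
        if (np.diff(cm) < 0).any():
            raise ValueError(f"arm {arm}: cM positions decrease")
    return wmap


@dataclass(frozen=True)
class NullDistribution:
    """Sorted genome-wide maximum statistics from permutations or null sims.

    ``values`` is ascending; ``p_value`` implements the raw-proportion
    convention: P = fraction of null values >= the observed statistic, so 0
    is attainable when the observation beats every null draw.
    """

    values: np.ndarray
    n_perm: int
    seed: int
    statistic: str = "max_lod"

    def __post_init__(self) -> None:
        values = np.sort(np.asarray(self.values, dtype=float))
        if values.size == 0:
            raise ValueError("empty null distribution")
        if values.size != self.n_perm:
            raise ValueError("length of values must equal n_perm")
        object.__setattr__(self, "values", values)

    def p_value(self, stat, plus_one: bool = False):
        """Empirical genome-wide P for a statistic (scalar or array).

        With ``plus_one`` the (r+1)/(n+1) estimator is used instead of the
        raw proportion.
        """
        stat = np.asarray(stat, dtype=float)
        n_ge = self.values.size - np.searchsorted(self.values, stat, side="left")
        if plus_one:
            p = (n_ge + 1) / (self.values.size + 1)
        else:
            p = n_ge / self.values.size
        return p if stat.ndim else float(p)

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.values, q))
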