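"""Simulation-based power analyses.

Three designs:

* additive QTL power — simulate phenotypes with a known additive effect at
  a window drawn from the panel, score each simulated LOD against a
  genome-wide max-LOD permutation null, and report detection rates per
  effect size and per realized QTL heritability;
* epistasis power — the interaction-factor design: a focal QTL with a
  fixed additive effect, phenotypes modified by a partner window through
  the multiplier (1, (1+I)/2, I), scored against a null distribution of
  genome-wide maximum interaction LOD scores from additive-only
  simulations;
* meta-analysis power — resample k interaction P-values from per-I
  simulated P distributions and ask how often the Fisher-combined P (or
  the minimum P) beats the observed benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AncestryMatrix, ConfigurationError, NullDistribution
from .epistasis import InteractionScanner
from .meta import fisher_combined
from .scan import _additive_stats, qtl_h2
from .windows import retained_mask


@dataclass(frozen=True)
class EpistasisPowerBase:
    """Base additive model for the epistasis power design.

    Defaults are the intermediate-size pigmentation QTL used to anchor the
    power simulations: per-allele effect 0.035 on trait mean 0.3485 with
    residual SD 0.0697.
    """

    focal_window: object
    a: float = 0.035
    mu: float = 0.3485
    sigma: float = 0.0697

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")


def _binomial_se(power: np.ndarray, n: int) -> np.ndarray:
    return np.sqrt(power * (1.0 - power) / n)


def qtl_power_grid(
    matrix: AncestryMatrix,
    summary,
    null: NullDistribution,
    effects,
    n_sim: int = 1_000,
    mu: float = 0.0,
    sigma: float = 0.75,
    alpha: float = 0.10,
    seed: int = 0,
):
    """Additive-scan power across a grid of per-allele effects.

    Per simulation a target window is drawn uniformly from the
    non-excluded windows, a phenotype y = Normal(mu, sigma) + a*g is
    simulated, the LOD at the target window is scored against the
    genome-wide max-LOD ``null``, and detection means P <= alpha. Returns
    ``(grid, records)``: the per-effect power table and the per-simulation
    records (effect, window, lod, h2, p, detected) for secondary binning
    by realized heritability.
    """
    effects = list(effects)
    if not effects:
        raise ConfigurationError("effects grid is empty")
    keep = retained_mask(matrix, summary)
    cols = np.nonzero(keep)[0]
    if cols.size == 0:
        raise ConfigurationError("no eligible windows")
    rng = np.random.default_rng(seed)
    rows = []
    grid_rows = []
    for a in effects:
        detected = 0
        for _ in range(n_sim):
            j = int(rng.choice(cols))
            g = matrix.dosage[:, j]
            y = rng.normal(mu, sigma, matrix.n_rils) + a * g
            n, b, lod, degen, _ = _additive_stats(g[:, None], y)
            lod_j = float(lod[0])
            p = null.p_value(lod_j)
            det = p <= alpha
            detected += det
            rows.append(
                {
                    "a": a,
                    "window_id": matrix.windows[j],
                    "lod": lod_j,
                    "h2": qtl_h2(lod_j, int(n[0])),
                    "p": p,
                    "detected": det,
                }
            )
        power = detected / n_sim
        grid_rows.append(
            {
                "a": a,
                "n_sim": n_sim,
                "detections": detected,
                "power": power,
                "se": float(_binomial_se(np.asarray(power), n_sim)),
                "alpha": alpha,
            }
        )
    return pd.DataFrame(grid_rows), pd.DataFrame(rows)


def power_by_h2_bin(records: pd.DataFrame, lo: float, hi: float):
    """Detection rate among simulations with realized h2 in [lo, hi].

    Returns ``(power, n_in_bin)``; power is NaN when the bin is empty.
    """
    sel = records[(records["h2"] >= lo) & (records["h2"] <= hi)]
    if sel.empty:
        return float("nan"), 0
    return float(sel["detected"].mean()), int(len(sel))


def epistasis_null_distribution(
    matrix: AncestryMatrix,
    summary,
    base: EpistasisPowerBase,
    excluded_ci=(),
    n_sim: int = 10_000,
    seed: int = 0,
    batch_size: int = 256,
) -> NullDistribution:
    """Null distribution of the genome-wide max interaction LOD.

    Phenotypes are simulated additive-only at the focal window
    (y = Normal(mu, sigma) + a*g_focal, so heterozygotes get 1x and
    derived homozygotes 2x the per-allele effect); each simulation
    records the maximum interaction LOD of the focal window against all
    partners outside ``excluded_ci``.
    """
    scanner = InteractionScanner(
        matrix, base.focal_window, summary=summary, exclude_windows=excluded_ci
    )
    g1 = matrix.column(base.focal_window)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_sim)
    done = 0
    while done < n_sim:
        b = min(batch_size, n_sim - done)
        Y = rng.normal(base.mu, base.sigma, (matrix.n_rils, b)) + (base.a * g1)[:, None]
        maxima[done : done + b] = scanner.max_lods(Y)
        done += b
    return NullDistribution(
        maxima, n_perm=n_sim, seed=seed, statistic="max_interaction_lod_null_sim"
    )


def epistasis_power(
    matrix: AncestryMatrix,
    base: EpistasisPowerBase,
    partner,
    null: NullDistribution,
    I_grid,
    n_sim: int = 1_000,
    alpha: float = 0.05,
    seed: int = 0,
    summary=None,
    excluded_ci=(),
    statistic: str = "max",
    batch_size: int = 256,
):
    """Power to detect the interaction-factor model at each I.

    Per simulation the focal effect is multiplied by 1, (1+I)/2 or I
    according to the partner dosage; the test statistic is the genome-wide
    maximum interaction LOD over the same partner set as the null
    (``statistic="max"``) or the interaction LOD at the true partner
    (``statistic="at_partner"``). P = proportion of null values >= the
    statistic; power = proportion of simulations with P < alpha.
    Returns ``(grid, records)``.
    """
    I_grid = list(I_grid)
    if not I_grid:
        raise ConfigurationError("I grid is empty")
    if statistic not in ("max", "at_partner"):
        raise ConfigurationError("statistic must be 'max' or 'at_partner'")
    scanner = InteractionScanner(
        matrix, base.focal_window, summary=summary, exclude_windows=excluded_ci
    )
    if partner not in set(scanner.partner_ids):
        raise ConfigurationError("partner window not in the eligible partner set")
    partner_row = int(np.nonzero(scanner.partner_ids == partner)[0][0])
    g1 = matrix.column(base.focal_window)
    g2 = matrix.column(partner)
    rng = np.random.default_rng(seed)
    grid_rows = []
    rec_rows = []
    for I in I_grid:
        m = 1.0 + (I - 1.0) / 2.0 * g2
        shift = (m * base.a * g1)[:, None]
        stats_all = np.empty(n_sim)
        done = 0
        while done < n_sim:
            b = min(batch_size, n_sim - done)
            Y = rng.normal(base.mu, base.sigma, (matrix.n_rils, b)) + shift
            lods = scanner.lods_many(Y)
            if statistic == "max":
                stats_all[done : done + b] = lods.max(axis=0)
            else:
                stats_all[done : done + b] = lods[partner_row]
            done += b
        p = null.p_value(stats_all)
        detected = p < alpha
        power = float(detected.mean())
        grid_rows.append(
            {
                "I": I,
                "n_sim": n_sim,
                "detections": int(detected.sum()),
                "power": power,
                "se": float(_binomial_se(np.asarray(power), n_sim)),
                "alpha": alpha,
            }
        )
        rec_rows.append(pd.DataFrame({"I": I, "stat": stats_all, "p": p, "detected": detected}))
    return pd.DataFrame(grid_rows), pd.concat(rec_rows, ignore_index=True)


def meta_power(
    sim_p_by_I: dict,
    k: int = 13,
    observed_fisher_p: float = 0.763,
    observed_min_p: float = 0.183,
    n_resample: int = 1_000,
    seed: int = 0,
    n_perm_for_zero: int = 10_000,
) -> pd.DataFrame:
    """Meta-analysis power by resampling k P-values per interaction factor.

    For each I, draws ``k`` P-values with replacement from the simulated
    P-value pool ``n_resample`` times and reports how often (1) the
    Fisher-combined P is <= the observed benchmark and (2) the minimum
    resampled P is below the observed minimum.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for I, pool in sim_p_by_I.items():
        pool = np.asarray(pool, dtype=float)
        if pool.size == 0:
            raise ConfigurationError(f"empty P-value pool for I={I}")
        fisher_hits = 0
        min_hits = 0
        for _ in range(n_resample):
            draw = rng.choice(pool, size=k, replace=True)
            draw_nz = np.where(draw == 0, 1.0 / (2.0 * n_perm_for_zero), draw)
            fisher_hits += fisher_combined(draw_nz).p <= observed_fisher_p
            min_hits += draw.min() < observed_min_p
        rows.append(
            {
                "I": I,
                "k": k,
                "n_resample": n_resample,
                "prop_fisher_le_observed": fisher_hits / n_resample,
                "prop_min_lt_observed": min_hits / n_resample,
            }
        )
    return pd.DataFrame(rows)
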