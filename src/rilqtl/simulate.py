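"""Synthetic RIL panels and phenotypes.

This module generates data with the statistical structure the scan modules
assume: biparental recombinant inbred lines genotyped as ancestry-dosage
windows along five chromosome arms, with skewed mean derived-ancestry
proportions, a low level of residual window heterozygosity in contiguous
tracts, and megabase-scale ancestry linkage. Defaults emulate the
Ethiopia-derived Drosophila melanogaster panel (278 RILs, 67.84% derived
ancestry, 8.71% window heterozygosity); a France-like configuration
(77.88% / 5.3%) is provided as well.

The ancestry process along each arm is a calibrated Markov tract model
rather than an explicit multi-generation pedigree simulation: breakpoints
fall as a Poisson process on the genetic (cM) axis at ``effective_meioses``
per Morgan and each tract draws derived ancestry independently. Residual
heterozygosity is overlaid as a second two-state tract process whose
stationary heterozygous fraction equals the target, and the tract-level
derived probability is analytically adjusted so the realized mean dosage/2
matches ``derived_ancestry_target`` despite the dosage-1 overlay.

Every simulator is deterministic given its config (one root seed per call).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AncestryMatrix, ConfigurationError, WINDOW_MAP_COLUMNS

#: (arm name, number of windows, arm genetic length in cM).
#: Window counts scale the fly genome down to ~1,030 windows while keeping
#: the five-arm layout and approximate arm map lengths.
DEFAULT_ARMS = [
    ("X", 200, 66.0),
    ("2L", 210, 55.0),
    ("2R", 205, 54.0),
    ("3L", 200, 55.0),
    ("3R", 215, 50.0),
]

#: Nominal physical window size in bp (the panels' windows average ~19 kb).
WINDOW_BP = 19_000
#: Nominal ancestral-population SNPs per window.
WINDOW_SNPS = 1_000


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of a synthetic RIL panel.

    ``effective_meioses`` is the breakpoint rate per Morgan and is the
    single knob controlling ancestry tract length (mean tract length =
    100/effective_meioses cM).
    """

    n_rils: int = 278
    arms: list = field(default_factory=lambda: list(DEFAULT_ARMS))
    derived_ancestry_target: float = 0.6784
    heterozygosity_target: float = 0.0871
    effective_meioses: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rils < 2:
            raise ConfigurationError("n_rils must be >= 2")
        if not self.arms:
            raise ConfigurationError("at least one arm required")
        for arm in self.arms:
            name, n_windows, length_cm = arm
            if n_windows < 1:
                raise ConfigurationError(f"arm {name}: n_windows must be >= 1")
            if length_cm <= 0:
                raise ConfigurationError(f"arm {name}: cM length must be > 0")
        if not 0.0 < self.derived_ancestry_target < 1.0:
            raise ConfigurationError("derived_ancestry_target must be in (0,1)")
        if not 0.0 <= self.heterozygosity_target < 1.0:
            raise ConfigurationError("heterozygosity_target must be in [0,1)")
        if self.effective_meioses <= 0:
            raise ConfigurationError("effective_meioses must be positive")
        p_tract = self.tract_derived_prob
        if not 0.0 < p_tract < 1.0:
            raise ConfigurationError(
                "derived_ancestry_target incompatible with heterozygosity_target "
                f"(implied tract probability {p_tract:.3f} outside (0,1))"
            )

    @property
    def tract_derived_prob(self) -> float:
        """Bernoulli probability of derived ancestry per homozygous tract.

        Heterozygous windows contribute dosage 1 (= proportion 0.5), so
        hitting the panel target p requires tracts at
        p' = (p - h/2) / (1 - h).
        """
        h = self.heterozygosity_target
        return (self.derived_ancestry_target - h / 2.0) / (1.0 - h)


def ethiopia_panel_config(seed: int = 0, **kwargs) -> PanelConfig:
    """Ethiopia-panel-like defaults (278 RILs, 67.84% derived, 8.71% het)."""
    return PanelConfig(seed=seed, **kwargs)


def france_panel_config(seed: int = 0, **kwargs) -> PanelConfig:
    """France-panel-like defaults (328 RILs, 77.88% derived, 5.3% het)."""
    kwargs.setdefault("n_rils", 328)
    kwargs.setdefault("derived_ancestry_target", 0.7788)
    kwargs.setdefault("heterozygosity_target", 0.053)
    return PanelConfig(seed=seed, **kwargs)


@dataclass(frozen=True)
class AdditiveSimConfig:
    """Additive single-QTL phenotype model: y = N(mu, sigma) + a * dosage."""

    mu: float = 0.0
    sigma: float = 0.75
    a: float = 0.0
    target_window: object = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")


@dataclass(frozen=True)
class EpistasisSimConfig:
    """Two-locus interaction model with interaction factor I.

    The focal additive effect is multiplied per RIL by 1, (1+I)/2 or I for
    partner dosage 0, 1 or 2. I = 1 recovers the additive model; I = 0 is
    masking epistasis; negative I is sign epistasis; I > 1 positive
    epistasis. Values outside the explored range [-2, 4] are permitted but
    flagged with a warning.
    """

    mu: float = 0.0
    sigma: float = 0.75
    a: float = 0.0
    focal_window: object = None
    partner_window: object = None
    I: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")
        if self.focal_window == self.partner_window:
            raise ConfigurationError("focal and partner windows must differ")
        if not -2.0 <= self.I <= 4.0:
            warnings.warn(
                f"interaction factor I={self.I} outside the explored range [-2, 4]",
                stacklevel=2,
            )


def _tract_breakpoints(rng: np.random.Generator, length_cm: float, rate_per_cm: float):
    """Breakpoint positions of a Poisson tract process on [0, length_cm]."""
    pos = []
    x = 0.0
    if rate_per_cm > 0:
        while True:
            x += rng.exponential(1.0 / rate_per_cm)
            if x >= length_cm:
                break
            pos.append(x)
    return np.asarray(pos)


def _arm_window_map(arm_name: str, n_windows: int, length_cm: float, offset: int):
    ids = [f"{arm_name}_w{i:04d}" for i in range(n_windows)]
    starts = np.arange(n_windows, dtype=np.int64) * WINDOW_BP
    cm_mid = (np.arange(n_windows) + 0.5) * (length_cm / n_windows)
    return pd.DataFrame(
        {
            "window_id": ids,
            "arm": arm_name,
            "start": starts,
            "end": starts + WINDOW_BP,
            "cM": cm_mid,
            "n_snps": WINDOW_SNPS,
        }
    )


def simulate_panel(config: PanelConfig):
    """Simulate a RIL panel: returns ``(AncestryMatrix, window map)``.

    Per RIL and arm, a homozygous ancestry mosaic is drawn from the Poisson
    tract process (dosage 0 or 2 per tract), then heterozygous tracts with
    stationary frequency ``heterozygosity_target`` overwrite dosage with 1.
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    wmap = pd.concat(
        [
            _arm_window_map(name, n, cm, i)
            for i, (name, n, cm) in enumerate(config.arms)
        ],
        ignore_index=True,
    )[WINDOW_MAP_COLUMNS]

    p_tract = config.tract_derived_prob
    h = config.heterozygosity_target
    rate = config.effective_meioses / 100.0  # breakpoints per cM
    # Heterozygous tracts: mean length = half the homozygous tract scale,
    # hazard out of the homozygous state set so stationary P(het) = h.
    het_out_rate = 2.0 * rate
    het_in_rate = het_out_rate * h / (1.0 - h) if h > 0 else 0.0

    dosage = np.empty((config.n_rils, len(wmap)), dtype=float)
    col0 = 0
    for name, n_windows, length_cm in config.arms:
        cm_mid = (np.arange(n_windows) + 0.5) * (length_cm / n_windows)
        for i in range(config.n_rils):
            bp = _tract_breakpoints(rng, length_cm, rate)
            states = rng.random(bp.size + 1) < p_tract
            seg = np.searchsorted(bp, cm_mid)
            arm_dosage = np.where(states[seg], 2.0, 0.0)
            if h > 0:
                arm_dosage[_het_mask(rng, cm_mid, length_cm, het_in_rate, het_out_rate)] = 1.0
            dosage[i, col0 : col0 + n_windows] = arm_dosage
        col0 += n_windows

    rils = np.array([f"RIL{i:04d}" for i in range(config.n_rils)], dtype=object)
    matrix = AncestryMatrix(rils, wmap["window_id"].to_numpy(dtype=object), dosage)
    return matrix, wmap


def _het_mask(rng, cm_mid, length_cm, in_rate, out_rate):
    """Boolean mask of windows covered by heterozygous tracts.

    Alternating-renewal process along the cM axis: exponential homozygous
    gaps (rate ``in_rate``) and heterozygous tracts (rate ``out_rate``);
    started at stationarity.
    """
    h = in_rate / (in_rate + out_rate)
    mask = np.zeros(cm_mid.size, dtype=bool)
    x = 0.0
    het = rng.random() < h
    while x < length_cm:
        seg_rate = out_rate if het else in_rate
        seg_len = rng.exponential(1.0 / seg_rate) if seg_rate > 0 else np.inf
        if het:
            mask |= (cm_mid >= x) & (cm_mid < x + seg_len)
        x += seg_len
        het = not het
    return mask


def simulate_additive_phenotype(panel: AncestryMatrix, cfg: AdditiveSimConfig) -> np.ndarray:
    """Phenotype vector y_i = Normal(mu, sigma) + a * dosage_i at the target.

    RILs with a missing call at the target window receive NaN. Aligned to
    ``panel.rils``; deterministic under ``cfg.seed``.
    """
    g = panel.column(cfg.target_window)
    rng = np.random.default_rng(cfg.seed)
    y = rng.normal(cfg.mu, cfg.sigma, panel.n_rils) + cfg.a * g
    return y


def simulate_epistatic_phenotype(panel: AncestryMatrix, cfg: EpistasisSimConfig) -> np.ndarray:
    """Phenotype under the interaction-factor model.

    y_i = Normal(mu, sigma) + m_i * a * g_focal,i with multiplier
    m_i = 1, (1+I)/2 or I for partner dosage 0, 1, 2. Equivalent to a
    product-term model with interaction coefficient a*(I-1)/2.
    """
    g1 = panel.column(cfg.focal_window)
    g2 = panel.column(cfg.partner_window)
    m = 1.0 + (cfg.I - 1.0) / 2.0 * g2
    rng = np.random.default_rng(cfg.seed)
    return rng.normal(cfg.mu, cfg.sigma, panel.n_rils) + m * cfg.a * g1


def simulate_gxe_phenotypes(panel, window, effects_by_env, sigma, seed=0) -> pd.DataFrame:
    """Per-environment phenotypes for the same RILs.

    ``effects_by_env`` maps environment label -> (mu_e, a_e); within each
    environment y = Normal(mu_e, sigma) + a_e * dosage. Returns a tidy
    table with columns ril, env, phenotype.
    """
    if not effects_by_env:
        raise ConfigurationError("effects_by_env must contain at least one environment")
    if sigma <= 0:
        raise ConfigurationError("sigma must be > 0")
    g = panel.column(window)
    rng = np.random.default_rng(seed)
    frames = []
    for env in effects_by_env:
        mu_e, a_e = effects_by_env[env]
        y = rng.normal(mu_e, sigma, panel.n_rils) + a_e * g
        frames.append(pd.DataFrame({"ril": panel.rils, "env": env, "phenotype": y}))
    return pd.concat(frames, ignore_index=True)


def simulate_snp_matrix(n_pop1, n_pop2, n_snps, freq_model, seed=0):
    """Biallelic diploid genotypes for two populations.

    ``freq_model`` is a pair ``(p1, p2)`` of derived-allele frequencies,
    each a scalar or length-``n_snps`` array. Returns ``(genotypes,
    labels)`` where genotypes is an ``(n_pop1+n_pop2, n_snps)`` 0/1/2
    matrix and labels is an array of ``"pop1"``/``"pop2"``.
    """
    if n_pop1 < 2 or n_pop2 < 2:
        raise ConfigurationError("each population needs >= 2 samples")
    if n_snps < 1:
        raise ConfigurationError("n_snps must be >= 1")
    p1 = np.broadcast_to(np.asarray(freq_model[0], dtype=float), (n_snps,))
    p2 = np.broadcast_to(np.asarray(freq_model[1], dtype=float), (n_snps,))
    rng = np.random.default_rng(seed)
    g1 = rng.binomial(2, p1, size=(n_pop1, n_snps)).astype(float)
    g2 = rng.binomial(2, p2, size=(n_pop2, n_snps)).astype(float)
    labels = np.array(["pop1"] * n_pop1 + ["pop2"] * n_pop2, dtype=object)
    return np.vstack([g1, g2]), labels


def mask_missing(matrix: AncestryMatrix, fraction: float, seed: int = 0) -> AncestryMatrix:
    """Return a copy with a random fraction of calls set to missing."""
    if not 0.0 <= fraction < 1.0:
        raise ConfigurationError("fraction must be in [0,1)")
    rng = np.random.default_rng(seed)
    dosage = matrix.dosage.copy()
    mask = rng.random(dosage.shape) < fraction
    dosage[mask] = np.nan
    return AncestryMatrix(matrix.rils, matrix.windows, dosage)
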