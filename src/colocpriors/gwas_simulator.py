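"""Synthetic case-control GWAS summary statistics under H3/H4.

The generator follows the classical single-causal-variant construction for
marginal association z-scores: given a causal variant c with log-odds
effect gamma, the expected z-score of variant i is

    mu_i = r_{i,c} * gamma / se_c,
    se_c = [2 f_c (1 - f_c) * phi (1 - phi) * N]^{-1/2},

where r is the allelic correlation (LD), f the allele frequency, phi the
case fraction and N the total sample size; the observed z-vector is a
single multivariate-normal draw with mean mu and covariance equal to the
LD matrix.  Haplotypes are simulated blockwise with autoregressive latent
correlation, standing in for a reference panel; the LD and MAF fed to the
z-score model are the empirical values computed from those haplotypes.

Study-design defaults mirror a moderately powered molecular-QTL setting:
2,000 cases and 2,000 controls, the causal effect drawn as the maximum of
100 N(0, 0.0025) variables (i.e. variance 0.0025, sd 0.05), and a
simulated region only accepted once its minimum two-sided p-value falls
below 5e-6 — colocalisation is only ever attempted where there is at
least a moderate association signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .region_data import LDMatrix, RegionSummaryStats
from .prior_sources import DistanceDensity, density_to_weights

__all__ = [
    "SimConfig",
    "SimulatedPair",
    "SimulationError",
    "simulate_haplotypes",
    "draw_effect",
    "expected_z",
    "simulate_stats",
    "simulate_pair",
]


class SimulationError(RuntimeError):
    """A simulation failed to satisfy its acceptance rule."""

    def __init__(self, message: str, attempts: int = 0):
        super().__init__(message)
        self.attempts = attempts


@dataclass(frozen=True)
class SimConfig:
    """Study design and genetic architecture of a simulated region.

    ``ld_model`` selects the latent correlation structure of the synthetic
    haplotypes: ``"ar"`` gives autoregressive decay within blocks (gradual
    fall-off with distance, coefficient ``ld_decay``), ``"exchangeable"``
    gives an LD plateau — every pair within a block shares latent
    correlation ``ld_decay``, mimicking the broad high-LD blocks seen at
    loci like the PTPN22 region.
    """

    n_variants: int = 500
    n_cases: int = 2000
    n_controls: int = 2000
    maf_range: Tuple[float, float] = (0.05, 0.5)
    ld_block_sizes: Optional[Sequence[int]] = None
    ld_decay: float = 0.9
    ld_model: str = "ar"
    n_haplotypes: int = 2000
    effect_draws: int = 100
    effect_var: float = 0.0025
    min_p: float = 5e-6
    max_attempts: int = 2000
    seed: Optional[int] = None

    def __post_init__(self):
        for name in ("n_variants", "n_cases", "n_controls", "n_haplotypes",
                     "effect_draws", "max_attempts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must lie in [0, 1)")
        if self.ld_model not in ("ar", "exchangeable"):
            raise ValueError("ld_model must be 'ar' or 'exchangeable'")
        if not 0.0 < self.min_p < 1.0:
            raise ValueError("min_p must lie in (0, 1)")
        if self.effect_var <= 0:
            raise ValueError("effect_var must be positive")

    @property
    def case_fraction(self) -> float:
        return self.n_cases / (self.n_cases + self.n_controls)

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @classmethod
    def high_ld(cls, n_variants: int = 500, seed: Optional[int] = None, **kw) -> "SimConfig":
        """Gradual-decay high-LD region: one AR(0.99) block spanning the
        region, common variants only.  Correlation falls off slowly with
        distance, so nearby variants are near-proxies but the two ends of
        the region are distinguishable."""
        return cls(n_variants=n_variants, ld_model="ar", ld_decay=0.99,
                   ld_block_sizes=[n_variants], maf_range=(0.1, 0.5),
                   seed=seed, **kw)

    @classmethod
    def ld_plateau(cls, n_variants: int = 500, seed: Optional[int] = None, **kw) -> "SimConfig":
        """Plateau high-LD region: two exchangeable blocks with latent
        correlation 0.97, emulating loci where a single haplotype block
        spans hundreds of kb and distinct causal variants are hard to
        tell apart."""
        half = n_variants // 2
        return cls(n_variants=n_variants, ld_model="exchangeable", ld_decay=0.97,
                   ld_block_sizes=[half, n_variants - half], maf_range=(0.1, 0.5),
                   seed=seed, **kw)


def _block_sizes(config: SimConfig) -> list:
    if config.ld_block_sizes is not None:
        sizes = list(config.ld_block_sizes)
        total = sum(sizes)
        if total < config.n_variants:
            raise ValueError("ld_block_sizes cover fewer variants than n_variants")
        # trim the final block to the region size
        out, acc = [], 0
        for s in sizes:
            if acc + s >= config.n_variants:
                out.append(config.n_variants - acc)
                return [s for s in out if s > 0]
            out.append(s)
            acc += s
        return out
    size = 50
    full, rem = divmod(config.n_variants, size)
    return [size] * full + ([rem] if rem else [])


def simulate_haplotypes(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[np.ndarray, LDMatrix, np.ndarray]:
    """Binary haplotypes with blockwise autoregressive LD.

    Latent Gaussians follow an AR(1) process with coefficient
    ``ld_decay`` within each block (independent across blocks) and are
    thresholded at each variant's target allele frequency.  Returns the
    haplotype matrix (n_haplotypes x n_variants), the empirical LD matrix
    and the empirical minor allele frequencies.  Monomorphic columns are
    resampled with a warning.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_hap, q = config.n_haplotypes, config.n_variants
    target = rng.uniform(*config.maf_range, size=q)

    z = np.empty((n_hap, q))
    col = 0
    rho = config.ld_decay
    for size in _block_sizes(config):
        if config.ld_model == "exchangeable":
            shared = rng.standard_normal(n_hap)[:, None]
            block = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal((n_hap, size))
        else:
            block = np.empty((n_hap, size))
            block[:, 0] = rng.standard_normal(n_hap)
            innov = np.sqrt(1.0 - rho**2)
            for j in range(1, size):
                block[:, j] = rho * block[:, j - 1] + innov * rng.standard_normal(n_hap)
        z[:, col : col + size] = block
        col += size

    hap = (z < sps.norm.ppf(target)[None, :]).astype(np.int8)

    freq = hap.mean(axis=0)
    mono = (freq == 0) | (freq == 1)
    tries = 0
    while np.any(mono):
        tries += 1
        if tries > 50:
            raise SimulationError("could not resample monomorphic sites")
        warnings.warn(f"resampling {mono.sum()} monomorphic site(s)", stacklevel=2)
        for j in np.where(mono)[0]:
            hap[:, j] = (rng.standard_normal(n_hap) < sps.norm.ppf(target[j])).astype(np.int8)
        freq = hap.mean(axis=0)
        mono = (freq == 0) | (freq == 1)

    maf = np.minimum(freq, 1.0 - freq)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(hap.astype(float), rowvar=False)
    np.fill_diagonal(r, 1.0)
    ids = np.array([f"v{j}" for j in range(q)], dtype=object)
    return hap, LDMatrix(ids, r), maf


def draw_effect(config: SimConfig, rng: Optional[np.random.Generator] = None) -> float:
    """Causal log-odds effect: the maximum of ``effect_draws`` i.i.d.
    N(0, effect_var) variables (positive with overwhelming probability)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    draws = rng.normal(0.0, np.sqrt(config.effect_var), size=config.effect_draws)
    return float(draws.max())


def expected_z(
    causal: int,
    gamma: float,
    ld: LDMatrix,
    maf: np.ndarray,
    config: SimConfig,
) -> Tuple[np.ndarray, np.ndarray]:
    """Expected marginal z-scores and per-variant standard errors.

    Returns (mu, se) with mu_i = r_{i,c} * gamma / se_c and
    se_i = [2 f_i (1 - f_i) phi (1 - phi) N]^{-1/2}.
    """
    maf = np.asarray(maf, dtype=float)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf values must lie in (0, 0.5]")
    phi = config.case_fraction
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * phi * (1.0 - phi) * config.n_total)
    mu_c = gamma / se[causal]
    mu = ld.r[:, causal] * mu_c
    return mu, se


def _psd_factor(r: np.ndarray, clip: float = 1e-10) -> np.ndarray:
    """Matrix square root of the LD matrix, repairing tiny negative
    eigenvalues (clipped at ``clip``) with a warning."""
    vals, vecs = np.linalg.eigh(r)
    if vals.min() < -1e-8:
        warnings.warn(
            f"LD matrix not positive semi-definite (min eigenvalue {vals.min():.2e}); "
            "clipping eigenvalues",
            stacklevel=3,
        )
    vals = np.clip(vals, clip, None)
    return vecs * np.sqrt(vals)[None, :]


def simulate_stats(
    causal: int,
    gamma: float,
    ld: LDMatrix,
    maf: np.ndarray,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    positions: Optional[np.ndarray] = None,
    chromosome: str = "1",
    trait_id: str = "sim",
    factor: Optional[np.ndarray] = None,
) -> Tuple[RegionSummaryStats, int]:
    """Draw accepted summary statistics for one trait.

    z-vectors are drawn from MVN(mu, LD) until the minimum two-sided
    p-value falls below ``config.min_p``; the first accepted draw is
    returned together with the number of attempts used.  Exhausting
    ``max_attempts`` raises :class:`SimulationError`.
    ``factor`` may carry a precomputed matrix square root of the LD matrix.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    q = len(maf)
    mu, se = expected_z(causal, gamma, ld, maf, config)
    if factor is None:
        factor = _psd_factor(ld.r)
    z_crit = sps.norm.isf(config.min_p / 2.0)

    for attempt in range(1, config.max_attempts + 1):
        z = mu + factor @ rng.standard_normal(q)
        if np.abs(z).max() > z_crit:
            if positions is None:
                positions = np.arange(1, q + 1)
            p = 2.0 * sps.norm.sf(np.abs(z))
            stats = RegionSummaryStats(
                trait_id=trait_id,
                trait_type="case_control",
                variant_ids=ld.variant_ids,
                chromosome=chromosome,
                positions=np.asarray(positions, dtype=np.int64),
                beta=z * se,
                se=se,
                maf=maf,
                n=np.full(q, float(config.n_total)),
                case_fraction=config.case_fraction,
                p=p,
            )
            return stats, attempt
    raise SimulationError(
        f"no draw reached min p < {config.min_p:g} in {config.max_attempts} attempts",
        attempts=config.max_attempts,
    )


@dataclass(frozen=True)
class SimulatedPair:
    """Two synthetic summary-statistic sets with known ground truth."""

    stats1: RegionSummaryStats
    stats2: RegionSummaryStats
    hypothesis: str
    causal1: int
    causal2: int
    ld: LDMatrix
    attempts_used: Tuple[int, int]
    gamma: Tuple[float, float] = (np.nan, np.nan)

    def __post_init__(self):
        if self.hypothesis not in ("H3", "H4"):
            raise ValueError("hypothesis must be 'H3' or 'H4'")
        if self.hypothesis == "H4" and self.causal1 != self.causal2:
            raise ValueError("H4 requires causal1 == causal2")
        if self.hypothesis == "H3" and self.causal1 == self.causal2:
            raise ValueError("H3 requires causal1 != causal2")


def simulate_pair(
    hypothesis: str,
    prior: DistanceDensity,
    tss: int,
    strand: str,
    positions: np.ndarray,
    ld: LDMatrix,
    maf: np.ndarray,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    chromosome: str = "1",
    factor: Optional[np.ndarray] = None,
) -> SimulatedPair:
    """Simulate a pair of traits under a stated colocalisation hypothesis.

    The causal variant for trait 1 is sampled with probability
    proportional to the supplied distance density evaluated at each
    variant position.  Under H4 trait 2 shares that causal variant; under
    H3 trait 2's causal variant is sampled uniformly from all other
    variants.  Effects are drawn independently per trait.
    """
    if hypothesis not in ("H3", "H4"):
        raise ValueError("hypothesis must be 'H3' or 'H4'")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    q = len(maf)
    weights = density_to_weights(prior, positions, tss, strand, variant_ids=ld.variant_ids)
    prob = weights.w / weights.w.sum()
    causal1 = int(rng.choice(q, p=prob))
    if hypothesis == "H4":
        causal2 = causal1
    else:
        others = np.delete(np.arange(q), causal1)
        causal2 = int(rng.choice(others))

    if factor is None:
        factor = _psd_factor(ld.r)
    gamma1 = draw_effect(config, rng)
    gamma2 = draw_effect(config, rng)
    stats1, att1 = simulate_stats(
        causal1, gamma1, ld, maf, config, rng, positions, chromosome, "trait1", factor
    )
    stats2, att2 = simulate_stats(
        causal2, gamma2, ld, maf, config, rng, positions, chromosome, "trait2", factor
    )
    return SimulatedPair(
        stats1=stats1,
        stats2=stats2,
        hypothesis=hypothesis,
        causal1=causal1,
        causal2=causal2,
        ld=ld,
        attempts_used=(att1, att2),
        gamma=(gamma1, gamma2),
    )
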