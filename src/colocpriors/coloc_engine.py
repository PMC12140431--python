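"""Colocalisation posteriors for two traits with variant-specific priors.

The model assumes at most one causal variant per trait in the region and
enumerates the five hypotheses

    H0: no association with either trait,
    H1: association with trait 1 only,
    H2: association with trait 2 only,
    H3: association with both traits, distinct causal variants,
    H4: association with both traits, a shared causal variant.

Supplied non-negative weights w_{k,i} are converted into per-variant prior
probabilities by

    p_{k,i} = Q * p_k * w_{k,i} / sum_i w_{k,i},        k in {1, 2}
    p_{12,i} = (p_12 / (p_1 * p_2)) * p_{1,i} * p_{2,i}

so that the priors remain proportional to the weights while the total
prior mass on each hypothesis (sum_i p_{k,i} = Q * p_k, and
sum_i p_{12,i} = Q * p_12 when at most one trait is weighted) is exactly
what uniform priors would give.  Hypothesis posteriors are computed from
per-variant log Bayes factors by exact enumeration over all (Q+1)^2 causal
configurations, with the H3 double sum collapsed to a product-minus-
diagonal identity; :func:`brute_force_posterior` performs the literal
enumeration as an independent cross-check.
"""

from __future__ import annotations

import time
import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .bayes_factors import AbfConfig, log_abf
from .region_data import (
    ColocResult,
    LogBFVector,
    PriorWeights,
    RegionSummaryStats,
    ValidationError,
    harmonise,
)

__all__ = [
    "DEFAULT_BASE",
    "weights_to_priors",
    "combine_p12",
    "make_variant_priors",
    "coloc_from_lbf",
    "coloc_abf",
    "brute_force_posterior",
]

from .region_data import VariantPriors

#: Default scalar prior probabilities (p1, p2, p12); robust over a wide
#: range of GWAS/eQTL scenarios.
DEFAULT_BASE: Tuple[float, float, float] = (1e-4, 1e-4, 5e-6)

# Relative H3 prior mass below which the distinct-causal-variant hypothesis
# is treated as structurally unsupported (e.g. all weight on one variant).
_H3_STRUCTURAL_TOL = 1e-12


def weights_to_priors(w: np.ndarray, p_k: float, q: Optional[int] = None) -> np.ndarray:
    """Scale raw weights into per-variant prior probabilities.

    Returns ``Q * p_k * w / sum(w)``; the result always sums to exactly
    ``Q * p_k`` regardless of the scale of ``w``.
    """
    w = np.asarray(w, dtype=float)
    if q is None:
        q = len(w)
    elif q != len(w):
        raise ValidationError(f"Q={q} does not match weight vector length {len(w)}")
    if np.any(w < 0):
        raise ValidationError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValidationError("weights sum to zero; at least one must be positive")
    if not 0 < q * p_k < 1:
        raise ValidationError(f"total prior mass Q*p_k = {q * p_k:g} must lie in (0, 1)")
    return q * p_k * w / total


def combine_p12(p1_i: np.ndarray, p2_i: np.ndarray, base: Tuple[float, float, float]) -> np.ndarray:
    """Per-variant prior probability of shared causality.

    With uniform priors for both traits every entry reduces to the scalar
    p12.
    """
    p1, p2, p12 = base
    if p1 * p2 == 0:
        raise ValidationError("base priors p1 and p2 must be non-zero")
    p1_i = np.asarray(p1_i, dtype=float)
    p2_i = np.asarray(p2_i, dtype=float)
    if len(p1_i) != len(p2_i):
        raise ValidationError("p1_i and p2_i have different lengths")
    return (p12 / (p1 * p2)) * p1_i * p2_i


def _is_uniform(w: Optional[np.ndarray]) -> bool:
    if w is None:
        return True
    w = np.asarray(w, dtype=float)
    return bool(np.ptp(w) <= 1e-15 * max(1.0, abs(float(w[0]))))


def make_variant_priors(
    q: int,
    weights1: Optional[np.ndarray] = None,
    weights2: Optional[np.ndarray] = None,
    base: Tuple[float, float, float] = DEFAULT_BASE,
) -> VariantPriors:
    """Build the full per-variant prior triple for a region of Q variants.

    ``weights1``/``weights2`` are raw weight vectors (or None for uniform).
    When both traits carry non-uniform weights the two-trait prior is still
    the product form above, but its total mass can deviate from Q*p12; a
    warning then reports the realised H4 prior mass.  Weighting one trait
    at a time preserves all hypothesis-level prior masses exactly.
    """
    p1, p2, p12 = base
    w1 = np.ones(q) if weights1 is None else np.asarray(weights1, dtype=float)
    w2 = np.ones(q) if weights2 is None else np.asarray(weights2, dtype=float)
    p1_i = weights_to_priors(w1, p1, q)
    p2_i = weights_to_priors(w2, p2, q)
    p12_i = combine_p12(p1_i, p2_i, base)
    if not _is_uniform(w1) and not _is_uniform(w2):
        realised = p12_i.sum()
        if abs(realised - q * p12) > 1e-12 * q * p12:
            warnings.warn(
                "both traits carry non-uniform weights: realised H4 prior mass "
                f"{realised:.3e} differs from the uniform-prior mass {q * p12:.3e}",
                stacklevel=2,
            )
    m3 = p1_i.sum() * p2_i.sum() - float(p1_i @ p2_i)
    total = p1_i.sum() + p2_i.sum() + m3 + p12_i.sum()
    if total >= 1:
        raise ValidationError(
            f"total prior mass across hypotheses ({total:.4g}) reaches 1; "
            "reduce the base priors or the region size"
        )
    return VariantPriors(p1=p1_i, p2=p2_i, p12=p12_i, base=tuple(base))


def _hypothesis_log_masses(lbf1: np.ndarray, lbf2: np.ndarray, priors: VariantPriors) -> np.ndarray:
    """Log posterior numerators (prior mass x Bayes factor) for H0..H4."""
    p1, p2, p12 = priors.p1, priors.p2, priors.p12
    q = len(p1)

    s1p, s2p = p1.sum(), p2.sum()
    diag_p = float(p1 @ p2)
    m3p = s1p * s2p - diag_p
    s12p = p12.sum()
    h0p = 1.0 - s1p - s2p - m3p - s12p
    if h0p <= 0:
        raise ValidationError("prior mass on H0 is non-positive; priors are too large")

    l0 = np.log(h0p)
    l1 = logsumexp(lbf1, b=p1)
    l2 = logsumexp(lbf2, b=p2)
    l4 = logsumexp(lbf1 + lbf2, b=p12) if np.any(p12 > 0) else -np.inf

    if q < 2:
        warnings.warn("fewer than 2 variants: H3 is undefined and assigned zero mass", stacklevel=3)
        l3 = -np.inf
    elif m3p <= _H3_STRUCTURAL_TOL * max(s1p * s2p, np.finfo(float).tiny):
        # prior support for distinct causal variants is (numerically) empty
        l3 = -np.inf
    else:
        ldiag = logsumexp(lbf1 + lbf2, b=p1 * p2)
        d = ldiag - (l1 + l2)
        if d < 0:
            l3 = l1 + l2 + np.log1p(-np.exp(d))
        elif d <= 1e-12:
            warnings.warn(
                "H3 mass lost to floating-point cancellation; clamping PP.H3 to 0",
                stacklevel=3,
            )
            l3 = -np.inf
        else:
            raise ValidationError(
                "H3 numerator is negative beyond rounding tolerance; inputs are inconsistent"
            )
    return np.array([l0, l1, l2, l3, l4])


def _snp_h4(lbf1: np.ndarray, lbf2: np.ndarray, p12: np.ndarray) -> np.ndarray:
    if not np.any(p12 > 0):
        return np.zeros_like(p12)
    with np.errstate(divide="ignore"):
        terms = np.log(p12) + lbf1 + lbf2
    return np.exp(terms - logsumexp(terms))


def _softmax(log_masses: np.ndarray) -> np.ndarray:
    return np.exp(log_masses - logsumexp(log_masses))


def coloc_from_lbf(
    lbf1: LogBFVector,
    lbf2: LogBFVector,
    priors: Optional[VariantPriors] = None,
    weights1: Optional[PriorWeights] = None,
    weights2: Optional[PriorWeights] = None,
    base: Tuple[float, float, float] = DEFAULT_BASE,
    positions: Optional[np.ndarray] = None,
    mode: str = "log-bf",
) -> ColocResult:
    """Colocalisation posterior from per-variant log Bayes factors.

    The two vectors must already be harmonised to the same variant order.
    ``priors`` may be given directly; otherwise it is built from the
    (optional) weights and scalar base priors.
    """
    if list(lbf1.variant_ids) != list(lbf2.variant_ids):
        raise ValidationError("lbf vectors are not harmonised to the same variant order")
    q = len(lbf1.lbf)
    if priors is None:
        w1 = weights1.align(lbf1.variant_ids) if weights1 is not None else None
        w2 = weights2.align(lbf2.variant_ids) if weights2 is not None else None
        priors = make_variant_priors(q, w1, w2, base)
    elif priors.n_variants != q:
        raise ValidationError("priors do not match the number of variants")

    log_masses = _hypothesis_log_masses(lbf1.lbf, lbf2.lbf, priors)
    pp = _softmax(log_masses)
    return ColocResult(
        pp=pp,
        snp_h4=_snp_h4(lbf1.lbf, lbf2.lbf, priors.p12),
        variant_ids=lbf1.variant_ids,
        priors=priors,
        lbf1=lbf1.lbf,
        lbf2=lbf2.lbf,
        positions=positions,
        meta={"Q": q, "mode": mode, "base": tuple(priors.base)},
    )


def coloc_abf(
    stats1: RegionSummaryStats,
    stats2: RegionSummaryStats,
    weights1: Optional[PriorWeights] = None,
    weights2: Optional[PriorWeights] = None,
    base: Tuple[float, float, float] = DEFAULT_BASE,
    config: AbfConfig = AbfConfig(),
) -> ColocResult:
    """Full colocalisation pipeline from two sets of summary statistics.

    harmonise -> Wakefield log-ABF per trait -> variant-specific priors ->
    hypothesis posteriors.
    """
    s1, s2 = harmonise(stats1, stats2)
    lbf1 = log_abf(s1, config)
    lbf2 = log_abf(s2, config)
    t0 = time.perf_counter()
    result = coloc_from_lbf(
        lbf1,
        lbf2,
        weights1=weights1,
        weights2=weights2,
        base=base,
        positions=s1.positions,
        mode="sumstats",
    )
    result.meta["runtime_s"] = time.perf_counter() - t0
    result.meta["trait1"] = s1.trait_id
    result.meta["trait2"] = s2.trait_id
    return result


def brute_force_posterior(
    lbf1: LogBFVector,
    lbf2: LogBFVector,
    priors: VariantPriors,
) -> ColocResult:
    """Reference posterior by explicit enumeration of all (Q+1)^2 configurations.

    Each configuration assigns trait 1's causal variant to {none, 1..Q} and
    likewise for trait 2; its prior mass is p_{1,i}, p_{2,j}, p_{1,i}p_{2,j}
    (i != j) or p_{12,i} (i == j), with the remainder on the double-null, and
    its likelihood ratio is the product of the corresponding Bayes factors.
    Quadratic in Q; refuses Q > 12.  Exists as an independent oracle for
    :func:`coloc_from_lbf`.
    """
    if list(lbf1.variant_ids) != list(lbf2.variant_ids):
        raise ValidationError("lbf vectors are not harmonised to the same variant order")
    q = len(lbf1.lbf)
    if q > 12:
        raise ValueError("brute-force enumeration is limited to Q <= 12")
    p1, p2, p12 = priors.p1, priors.p2, priors.p12
    b1, b2 = lbf1.lbf, lbf2.lbf

    mass = p1.sum() + p2.sum() + (p1.sum() * p2.sum() - float(p1 @ p2)) + p12.sum()
    h0p = 1.0 - mass
    if h0p <= 0:
        raise ValidationError("prior mass on H0 is non-positive; priors are too large")

    with np.errstate(divide="ignore"):
        log_h0 = np.array([np.log(h0p)])
        log_h1 = np.log(p1) + b1
        log_h2 = np.log(p2) + b2
        pair = (np.log(p1) + b1)[:, None] + (np.log(p2) + b2)[None, :]
        off_diag = pair[~np.eye(q, dtype=bool)]
        log_h4 = np.log(p12) + b1 + b2

    log_masses = np.array(
        [
            log_h0[0],
            logsumexp(log_h1),
            logsumexp(log_h2),
            logsumexp(off_diag) if q >= 2 else -np.inf,
            logsumexp(log_h4) if np.any(p12 > 0) else -np.inf,
        ]
    )
    pp = _softmax(log_masses)
    return ColocResult(
        pp=pp,
        snp_h4=_snp_h4(b1, b2, p12),
        variant_ids=lbf1.variant_ids,
        priors=priors,
        lbf1=b1,
        lbf2=b2,
        meta={"Q": q, "mode": "brute-force", "base": tuple(priors.base)},
    )
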