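"""Wakefield approximate Bayes factors and weighted single-trait fine-mapping.

For a variant with effect estimate ``beta`` and standard error ``se``, the
approximate Bayes factor against the null under a normal effect prior
N(0, W) depends only on z = beta/se, V = se² and W:

    lABF = 0.5 * [ln(1 - r) + r * z²],   r = W / (V + W).

All Bayes-factor arithmetic is carried out in natural-log space with
log-sum-exp reductions: z² can reach several thousand in strongly
associated loci and would overflow linear space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .region_data import LogBFVector, PriorWeights, RegionSummaryStats, ValidationError

__all__ = ["AbfConfig", "log_abf", "finemap_posterior", "FinemapResult"]


@dataclass(frozen=True)
class AbfConfig:
    """Prior effect-size scales for the approximate Bayes factor.

    sd_prior_quant : float
        Prior SD of the standardized effect for quantitative traits
        (default 0.15).
    sd_prior_cc : float
        Prior SD of the log-odds effect for case-control traits
        (default 0.2).
    sdY : float, optional
        Trait standard deviation for quantitative traits; the effective
        prior SD is ``sd_prior_quant * sdY``.  Default 1 (effects already
        on the per-SD scale).
    """

    sd_prior_quant: float = 0.15
    sd_prior_cc: float = 0.2
    sdY: Optional[float] = None

    def __post_init__(self):
        if self.sd_prior_quant <= 0 or self.sd_prior_cc <= 0:
            raise ValueError("prior effect standard deviations must be positive")
        if self.sdY is not None and self.sdY <= 0:
            raise ValueError("sdY must be positive")

    def prior_variance(self, trait_type: str) -> float:
        """W, the prior variance of the effect, for the given trait type."""
        if trait_type == "case_control":
            return self.sd_prior_cc ** 2
        sd = self.sd_prior_quant * (self.sdY if self.sdY is not None else 1.0)
        return sd ** 2


def log_abf(stats: RegionSummaryStats, config: AbfConfig = AbfConfig()) -> LogBFVector:
    """Per-variant log approximate Bayes factors for one trait."""
    w = config.prior_variance(stats.trait_type)
    if w <= 0:
        raise ValueError("prior effect variance W must be positive")
    v = stats.se ** 2
    z = stats.beta / stats.se
    r = w / (v + w)
    lbf = 0.5 * (np.log1p(-r) + r * z ** 2)
    return LogBFVector(stats.variant_ids, lbf)


@dataclass(frozen=True)
class FinemapResult:
    """Posterior over {no causal variant, each variant causal}.

    ``posterior`` has Q+1 entries: the null first, then one per variant in
    input order; it sums to 1.  ``pip`` is the causal-conditional posterior
    over variants (sums to 1), and ``credible_set`` the indices of the
    smallest variant set whose conditional mass reaches the requested level,
    ordered by decreasing posterior.
    """

    variant_ids: np.ndarray
    posterior: np.ndarray
    pip: np.ndarray
    credible_set: np.ndarray
    credible_level: float

    @property
    def null_posterior(self) -> float:
        return float(self.posterior[0])


def finemap_posterior(
    lbf: LogBFVector,
    weights: Optional[PriorWeights] = None,
    p: float = 1e-4,
    credible_level: float = 0.95,
) -> FinemapResult:
    """Single-trait fine-mapping posterior under at most one causal variant.

    The prior over the Q+1 outcomes is {1 - Q*p} for the null and the
    per-variant probabilities obtained by scaling ``p`` with the supplied
    weights (uniform when ``weights`` is omitted).
    """
    from .coloc_engine import weights_to_priors  # local import to avoid a cycle

    q = len(lbf.lbf)
    if not 0 < p < 1.0 / q:
        raise ValueError(f"p must lie in (0, 1/Q); got p={p} with Q={q}")
    if weights is None:
        p_i = np.full(q, p)
    else:
        p_i = weights_to_priors(weights.align(lbf.variant_ids), p, q)

    with np.errstate(divide="ignore"):
        log_num = np.concatenate(([np.log1p(-q * p)], np.log(p_i) + lbf.lbf))
    log_den = logsumexp(log_num)
    posterior = np.exp(log_num - log_den)

    cond = posterior[1:] / posterior[1:].sum()
    order = np.argsort(cond, kind="stable")[::-1]
    cum = np.cumsum(cond[order])
    k = int(np.searchsorted(cum, credible_level) + 1)
    k = min(k, q)
    return FinemapResult(
        variant_ids=lbf.variant_ids,
        posterior=posterior,
        pip=cond,
        credible_set=order[:k],
        credible_level=credible_level,
    )
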