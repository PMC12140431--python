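"""Domain types and file I/O for regional association summary statistics.

The unit of analysis throughout the package is a genomic region (typically a
1 Mb window around a gene's transcription start site) with per-variant
association results for one trait.  This module defines the containers the
rest of the package operates on — summary statistics, LD matrices, prior
weights and probabilities, log Bayes factor vectors, and colocalisation
results — together with TSV/JSON readers and writers for each.

Conventions
-----------
* Variant positions are 1-based base-pair coordinates.
* Effect sizes are log-odds for case-control traits and per-SD units for
  quantitative traits; standard errors are on the same scale.
* Inputs are assumed allele-harmonised upstream: :func:`harmonise` matches
  on variant id only and performs no strand or effect-allele flipping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "RegionSummaryStats",
    "LDMatrix",
    "PriorWeights",
    "VariantPriors",
    "LogBFVector",
    "ColocResult",
    "read_sumstats",
    "write_sumstats",
    "read_ld",
    "write_ld",
    "harmonise",
    "write_coloc_result",
    "read_weights",
    "write_weights",
]

SUMSTATS_COLUMNS = ("snp", "chr", "pos", "beta", "se", "maf", "n")


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant."""


def _as_str_array(x: Sequence) -> np.ndarray:
    return np.asarray(list(x), dtype=object)


@dataclass(frozen=True)
class RegionSummaryStats:
    """One trait's per-variant association results over a genomic window.

    Parameters
    ----------
    trait_id : str
        Label for the trait (e.g. a gene or phenotype id).
    trait_type : {"quantitative", "case_control"}
    variant_ids : array of str
        Unique variant labels, ordered to match all per-variant vectors.
    chromosome : str
    positions : int array
        1-based coordinates, sorted non-decreasing.
    beta, se : float arrays
        Effect sizes and their standard errors (se > 0).
    maf : float array
        Minor allele frequencies in (0, 0.5].
    n : float array
        Total sample size per variant.
    case_fraction : float, optional
        Fraction of cases; required iff ``trait_type == "case_control"``.
    p : float array, optional
        Two-sided p-values.  When absent they are recomputed from
        z = beta/se via the two-sided normal tail (see :meth:`pvalues`).
    """

    trait_id: str
    trait_type: str
    variant_ids: np.ndarray
    chromosome: str
    positions: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    maf: np.ndarray
    n: np.ndarray
    case_fraction: Optional[float] = None
    p: Optional[np.ndarray] = None

    def __post_init__(self):
        object.__setattr__(self, "variant_ids", _as_str_array(self.variant_ids))
        for name in ("positions", "beta", "se", "maf", "n"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=np.int64))
        if self.p is not None:
            object.__setattr__(self, "p", np.asarray(self.p, dtype=float))

        if self.trait_type not in ("quantitative", "case_control"):
            raise ValidationError(f"unknown trait_type {self.trait_type!r}")
        q = len(self.variant_ids)
        for name in ("positions", "beta", "se", "maf", "n"):
            if len(getattr(self, name)) != q:
                raise ValidationError(f"length of {name} does not match variant_ids")
        if self.p is not None and len(self.p) != q:
            raise ValidationError("length of p does not match variant_ids")
        if len(set(self.variant_ids)) != q:
            dupes = pd.Series(self.variant_ids).value_counts()
            dupes = list(dupes.index[dupes > 1])
            raise ValidationError(f"duplicate variant ids: {dupes}")
        bad_se = self.variant_ids[~(self.se > 0)]
        if len(bad_se):
            raise ValidationError(f"non-positive se for variants: {list(bad_se)}")
        if np.any(np.diff(self.positions) < 0):
            raise ValidationError("positions must be sorted non-decreasing")
        if np.any((self.maf <= 0) | (self.maf > 0.5)):
            bad = self.variant_ids[(self.maf <= 0) | (self.maf > 0.5)]
            raise ValidationError(f"maf outside (0, 0.5] for variants: {list(bad)}")
        if self.trait_type == "case_control":
            if self.case_fraction is None:
                raise ValidationError("case_fraction is required for case_control traits")
            if not 0 < self.case_fraction < 1:
                raise ValidationError("case_fraction must be in (0, 1)")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def pvalues(self) -> np.ndarray:
        """Two-sided p-values; recomputed from beta/se when not supplied."""
        if self.p is not None:
            return self.p
        z = self.beta / self.se
        return 2.0 * sps.norm.sf(np.abs(z))

    def subset(self, ids: Sequence[str]) -> "RegionSummaryStats":
        """Restrict to ``ids`` in the given order."""
        index = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            idx = np.array([index[v] for v in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} not present in {self.trait_id}") from None
        return RegionSummaryStats(
            trait_id=self.trait_id,
            trait_type=self.trait_type,
            variant_ids=self.variant_ids[idx],
            chromosome=self.chromosome,
            positions=self.positions[idx],
            beta=self.beta[idx],
            se=self.se[idx],
            maf=self.maf[idx],
            n=self.n[idx],
            case_fraction=self.case_fraction,
            p=None if self.p is None else self.p[idx],
        )


@dataclass(frozen=True)
class LDMatrix:
    """Square matrix of pairwise allelic correlations r in [-1, 1]."""

    variant_ids: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "variant_ids", _as_str_array(self.variant_ids))
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        q = len(self.variant_ids)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise FormatError(f"LD matrix must be square, got shape {r.shape}")
        if r.shape[0] != q:
            raise ValidationError("LD dimension does not match variant count")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValidationError("LD matrix not symmetric within 1e-8")
        if np.any(np.abs(np.diag(r) - 1.0) > 1e-6):
            raise ValidationError("LD diagonal deviates from 1 by more than 1e-6")

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        index = {v: i for i, v in enumerate(self.variant_ids)}
        idx = np.array([index[v] for v in ids], dtype=int)
        return LDMatrix(self.variant_ids[idx], self.r[np.ix_(idx, idx)])


@dataclass(frozen=True)
class PriorWeights:
    """Raw non-negative per-variant causality weights for one trait.

    These are the w_{k,i} supplied by a user or built by
    :mod:`colocpriors.prior_sources`; they are scale-free and only their
    ratios matter once normalised into prior probabilities.
    """

    variant_ids: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "variant_ids", _as_str_array(self.variant_ids))
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if len(w) != len(self.variant_ids):
            raise ValidationError("weight vector length does not match variant_ids")
        if np.any(w < 0) or np.any(~np.isfinite(w)):
            raise ValidationError("weights must be finite and non-negative")
        if not np.any(w > 0):
            raise ValidationError("at least one weight must be positive")

    def align(self, ids: Sequence[str]) -> np.ndarray:
        """Weight vector reordered to ``ids``; every id must be present."""
        index = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            idx = np.array([index[v] for v in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"no prior weight for variant {exc.args[0]!r}") from None
        return self.w[idx]


@dataclass(frozen=True)
class VariantPriors:
    """Normalised per-variant prior probabilities of causality.

    ``p1[i]`` / ``p2[i]`` are the prior probabilities that variant i is
    causal for trait 1 / trait 2 only; ``p12[i]`` that it is causal for
    both.  ``base`` is the scalar triple (p1, p2, p12) these were scaled
    from; with uniform weights every entry equals the corresponding base
    value.
    """

    p1: np.ndarray
    p2: np.ndarray
    p12: np.ndarray
    base: tuple

    def __post_init__(self):
        for name in ("p1", "p2", "p12"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        q = len(self.p1)
        if len(self.p2) != q or len(self.p12) != q:
            raise ValidationError("prior vectors have mismatched lengths")
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if np.any(v < 0) or np.any(~np.isfinite(v)):
                raise ValidationError(f"{name} entries must be finite and non-negative")

    @property
    def n_variants(self) -> int:
        return len(self.p1)


@dataclass(frozen=True)
class LogBFVector:
    """Per-variant natural-log Bayes factors for one trait or signal."""

    variant_ids: np.ndarray
    lbf: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "variant_ids", _as_str_array(self.variant_ids))
        lbf = np.asarray(self.lbf, dtype=float)
        object.__setattr__(self, "lbf", lbf)
        if len(lbf) != len(self.variant_ids):
            raise ValidationError("lbf length does not match variant_ids")
        if np.any(~np.isfinite(lbf)):
            raise ValidationError("lbf values must be finite")


HYPOTHESES = ("PP.H0", "PP.H1", "PP.H2", "PP.H3", "PP.H4")


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities of the five colocalisation hypotheses.

    ``pp`` holds (PP.H0, …, PP.H4), summing to 1.  ``snp_h4`` is the
    per-variant posterior probability of being the shared causal variant,
    normalised within H4.  ``meta`` records the priors, Q and input mode.
    """

    pp: np.ndarray
    snp_h4: np.ndarray
    variant_ids: np.ndarray
    priors: VariantPriors
    meta: dict = field(default_factory=dict)
    lbf1: Optional[np.ndarray] = None
    lbf2: Optional[np.ndarray] = None
    positions: Optional[np.ndarray] = None

    def __post_init__(self):
        pp = np.asarray(self.pp, dtype=float)
        object.__setattr__(self, "pp", pp)
        object.__setattr__(self, "snp_h4", np.asarray(self.snp_h4, dtype=float))
        object.__setattr__(self, "variant_ids", _as_str_array(self.variant_ids))
        if pp.shape != (5,):
            raise ValidationError("pp must have exactly five entries")
        if np.any((pp < -1e-12) | (pp > 1 + 1e-12)):
            raise ValidationError("pp entries must lie in [0, 1]")
        if abs(pp.sum() - 1.0) > 1e-10:
            raise ValidationError("pp must sum to 1 within 1e-10")
        if pp[4] > 0 and abs(self.snp_h4.sum() - 1.0) > 1e-10:
            raise ValidationError("snp_h4 must sum to 1 within 1e-10 when PP.H4 > 0")

    def pp_dict(self) -> dict:
        return {h: float(v) for h, v in zip(HYPOTHESES, self.pp)}

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_sumstats(path, trait_type: str, trait_id: Optional[str] = None) -> RegionSummaryStats:
    """Read a TSV of summary statistics.

    Expected columns: ``snp chr pos beta se maf n`` plus ``s`` (case
    fraction) for case-control traits and optionally ``p``.  Rows with
    missing beta or se are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chr": str},
                     float_precision="round_trip")
    required = list(SUMSTATS_COLUMNS)
    if trait_type == "case_control":
        required.append("s")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    n_before = len(df)
    df = df.dropna(subset=["beta", "se"])
    if len(df) < n_before:
        logger.info("dropped %d rows with missing beta/se from %s", n_before - len(df), path)
    bad_se = df.loc[~(df["se"] > 0), "snp"]
    if len(bad_se):
        raise ValidationError(f"non-positive se for variants: {list(bad_se)}")
    case_fraction = None
    if trait_type == "case_control":
        s = df["s"].to_numpy(dtype=float)
        if len(s) and np.ptp(s) > 1e-12:
            raise ValidationError("case fraction column 's' must be constant within a region")
        case_fraction = float(s[0]) if len(s) else None
    chroms = df["chr"].unique()
    if len(chroms) > 1:
        raise ValidationError(f"multiple chromosomes in one region: {list(chroms)}")
    df = df.sort_values("pos", kind="stable")
    return RegionSummaryStats(
        trait_id=trait_id or str(path),
        trait_type=trait_type,
        variant_ids=df["snp"].to_numpy(dtype=object),
        chromosome=str(chroms[0]) if len(chroms) else "NA",
        positions=df["pos"].to_numpy(dtype=np.int64),
        beta=df["beta"].to_numpy(dtype=float),
        se=df["se"].to_numpy(dtype=float),
        maf=df["maf"].to_numpy(dtype=float),
        n=df["n"].to_numpy(dtype=float),
        case_fraction=case_fraction,
        p=df["p"].to_numpy(dtype=float) if "p" in df.columns else None,
    )


def write_sumstats(stats: RegionSummaryStats, path) -> None:
    """Write summary statistics to TSV (inverse of :func:`read_sumstats`)."""
    data = {
        "snp": stats.variant_ids,
        "chr": [stats.chromosome] * stats.n_variants,
        "pos": stats.positions,
        "beta": stats.beta,
        "se": stats.se,
        "maf": stats.maf,
        "n": stats.n,
    }
    if stats.case_fraction is not None:
        data["s"] = [stats.case_fraction] * stats.n_variants
    if stats.p is not None:
        data["p"] = stats.p
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_ld(path) -> LDMatrix:
    """Read a dense square LD matrix (TSV with variant-id header and index).

    The matrix is symmetrised as (M + Mᵀ)/2 and the diagonal is set to
    exactly 1 after checking it deviates by at most 1e-6.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    m = df.to_numpy(dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise FormatError(f"LD matrix in {path} is not square: shape {m.shape}")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise FormatError(f"LD row and column ids disagree in {path}")
    if np.any(np.abs(np.diag(m) - 1.0) > 1e-6):
        raise ValidationError(f"LD diagonal deviates from 1 by more than 1e-6 in {path}")
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return LDMatrix(df.columns.astype(str).to_numpy(dtype=object), m)


def write_ld(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(path, sep="\t")


def harmonise(stats1: RegionSummaryStats, stats2: RegionSummaryStats):
    """Restrict two regions to their shared variants, identically ordered.

    Matching is by variant id only (inputs are assumed allele-harmonised).
    The shared ids keep the order they have in ``stats1``.  After this the
    number of variants analysed, Q, is the intersection size.
    """
    if stats1.chromosome != stats2.chromosome:
        raise ValidationError(
            f"regions on different chromosomes: {stats1.chromosome} vs {stats2.chromosome}"
        )
    ids2 = set(stats2.variant_ids)
    shared = [v for v in stats1.variant_ids if v in ids2]
    if not shared:
        raise ValidationError("no shared variants between the two regions")
    return stats1.subset(shared), stats2.subset(shared)


def write_coloc_result(result: ColocResult, json_path, tsv_path=None) -> None:
    """Write a colocalisation result as JSON plus an optional per-variant TSV."""
    payload = {
        "pp": result.pp_dict(),
        "nsnps": int(len(result.variant_ids)),
        "meta": {k: v for k, v in result.meta.items()},
        "base_priors": {
            "p1": result.priors.base[0],
            "p2": result.priors.base[1],
            "p12": result.priors.base[2],
        },
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if tsv_path is not None:
        data = {
            "snp": result.variant_ids,
            "pos": result.positions if result.positions is not None else np.full(len(result.variant_ids), -1),
            "lbf1": result.lbf1 if result.lbf1 is not None else np.nan,
            "lbf2": result.lbf2 if result.lbf2 is not None else np.nan,
            "p1_i": result.priors.p1,
            "p2_i": result.priors.p2,
            "p12_i": result.priors.p12,
            "snp_h4": result.snp_h4,
        }
        pd.DataFrame(data).to_csv(tsv_path, sep="\t", index=False)


def read_weights(path) -> PriorWeights:
    """Read a per-variant weight vector from a TSV with columns ``snp w``."""
    df = pd.read_csv(path, sep="\t", dtype={"snp": str}, float_precision="round_trip")
    for col in ("snp", "w"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    return PriorWeights(
        variant_ids=df["snp"].to_numpy(dtype=object),
        w=df["w"].to_numpy(dtype=float),
    )


def write_weights(weights: PriorWeights, path) -> None:
    pd.DataFrame({"snp": weights.variant_ids, "w": weights.w}).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )
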