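"""Builders for per-variant prior weight vectors.

Four sources of variant-level prior information are supported:

* **eQTL-TSS distance densities** — an empirical density of the signed
  distance between significant eQTLs and their gene's transcription start
  site, estimated by Gaussian kernel density estimation with a
  Sheather-Jones plug-in bandwidth inflated 8-fold (to absorb uncertainty
  in the TSS location) and represented as 512 (distance, density) pairs
  over the data range.
* **ABC enhancer-gene link scores** — a variant inherits the median (over
  biosamples) activity-by-contact score of the enhancer it lies in;
  variants outside every enhancer receive the constant 0.0075, half the
  minimum score present in the public dataset (which is truncated at
  0.015).
* **Gnocchi non-coding constraint** — a variant takes the signed
  constraint score of its 1 kb region, or of the nearest scored region;
  scores are mapped to weights by a softmax over the region's variants.
* **PolyFun per-SNP heritability** — weights are the tabulated per-SNP
  variance estimates; SNPs without an entry receive the minimum entry
  present in the table.

All builders return weights aligned to the supplied variant list,
non-negative and not all zero, ready for Eq-style normalisation by the
colocalisation engine.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .region_data import FormatError, PriorWeights, ValidationError

__all__ = [
    "EqtlRecord",
    "DistanceDensity",
    "AbcRecord",
    "GnocchiRecord",
    "PolyFunRecord",
    "signed_distance",
    "top_eqtl_per_gene",
    "sheather_jones_bandwidth",
    "estimate_density",
    "density_to_weights",
    "abc_to_weights",
    "gnocchi_to_weights",
    "polyfun_to_weights",
    "read_eqtl_table",
    "read_abc_table",
    "read_gnocchi_table",
    "read_polyfun_table",
    "read_density",
    "write_density",
    "ABC_MISSING_SCORE",
    "DENSITY_GRID_SIZE",
]

#: Score given to a variant lying outside every enhancer interval: half the
#: minimum ABC score retained in the public enhancer-gene dataset (0.015).
ABC_MISSING_SCORE = 0.0075

#: Number of (distance, density) pairs representing an estimated density.
DENSITY_GRID_SIZE = 512

#: Positive floor applied when interpolating density weights, so that a
#: weight vector can never be identically zero.
DENSITY_WEIGHT_FLOOR = 1e-12


@dataclass(frozen=True)
class EqtlRecord:
    """A significant eQTL: variant position, gene TSS, strand and p-value."""

    gene_id: str
    variant_pos: int
    tss: int
    strand: str
    p_value: float
    variant_id: Optional[str] = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 < self.p_value <= 1:
            raise ValidationError(f"p_value must be in (0, 1], got {self.p_value}")


@dataclass(frozen=True)
class AbcRecord:
    """An enhancer-gene link (0-based half-open interval) with an ABC score."""

    chrom: str
    start: int
    end: int
    gene_id: str
    biosample: str
    score: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError("enhancer interval must have start < end")
        if self.score < 0:
            raise ValidationError("ABC score must be non-negative")


@dataclass(frozen=True)
class GnocchiRecord:
    """A 1 kb constraint region (0-based half-open) with a signed score."""

    chrom: str
    start: int
    end: int
    score: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError("region must have start < end")


@dataclass(frozen=True)
class PolyFunRecord:
    """A per-SNP heritability (variance) entry keyed by id and/or position."""

    chrom: str
    pos: int
    variance: float
    snp: Optional[str] = None

    def __post_init__(self):
        if self.variance < 0:
            raise ValidationError("per-SNP variance must be non-negative")


@dataclass(frozen=True)
class DistanceDensity:
    """An empirical eQTL-TSS signed-distance density on a 512-point grid.

    ``grid`` holds strictly increasing signed distances (bp), ``density``
    the non-negative density values at those points.  The trapezoid
    integral over the grid must fall in [0.9, 1.1]; some mass is
    legitimately lost when the kernel tails extend past the data range.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    window: int = 500_000
    source: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "density", dens)
        if len(grid) != DENSITY_GRID_SIZE or len(dens) != DENSITY_GRID_SIZE:
            raise ValidationError(f"density grid must have exactly {DENSITY_GRID_SIZE} pairs")
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("grid distances must be strictly increasing")
        if np.any(dens < 0):
            raise ValidationError("density values must be non-negative")
        if self.bandwidth <= 0:
            raise ValidationError("bandwidth must be positive")
        integral = np.trapezoid(dens, grid)
        if not 0.9 <= integral <= 1.1:
            raise ValidationError(
                f"density integrates to {integral:.3f}, outside [0.9, 1.1]"
            )

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def mode(self) -> float:
        """Grid distance with the maximal density value."""
        return float(self.grid[int(np.argmax(self.density))])


def signed_distance(pos: int, tss: int, strand: str) -> int:
    """Signed variant-TSS distance: downstream of transcription is positive.

    For a + strand gene d = pos - tss; for a - strand gene d = tss - pos.
    """
    if strand == "+":
        return pos - tss
    if strand == "-":
        return tss - pos
    raise ValidationError(f"strand must be '+' or '-', got {strand!r}")


def top_eqtl_per_gene(records: Sequence[EqtlRecord], alpha: float = 5e-8) -> List[EqtlRecord]:
    """Keep the single most significant genome-wide-significant eQTL per gene.

    Records with p >= ``alpha`` are discarded; among the rest, each gene
    keeps its minimum-p record.  Ties at the minimal p are broken by
    distance to the TSS, then by variant id order.
    """
    by_gene: Dict[str, List[EqtlRecord]] = {}
    for rec in records:
        if rec.p_value < alpha:
            by_gene.setdefault(rec.gene_id, []).append(rec)

    def _key(rec: EqtlRecord):
        return (
            rec.p_value,
            abs(signed_distance(rec.variant_pos, rec.tss, rec.strand)),
            rec.variant_id if rec.variant_id is not None else "",
        )

    return [min(recs, key=_key) for _, recs in sorted(by_gene.items())]


# ---------------------------------------------------------------------------
# Sheather-Jones solve-the-equation bandwidth
# ---------------------------------------------------------------------------

def _bin_pair_counts(x: np.ndarray, nb: int = 1000) -> Tuple[float, np.ndarray, np.ndarray]:
    """Bin the data and count ordered pairs by bin distance.

    Returns (bin width, counts of unordered pairs at each bin distance,
    per-bin counts).  The pairwise sums in the plug-in functionals are then
    O(nb) per evaluation instead of O(n^2).
    """
    xmin, xmax = x.min(), x.max()
    rang = (xmax - xmin) * 1.01
    if rang <= 0:
        raise ValidationError("all observations identical; bandwidth is undefined")
    dd = rang / nb
    ii = np.minimum((x - xmin) // dd, nb - 1).astype(np.int64)
    cnt = np.bincount(ii, minlength=nb).astype(float)
    # full discrete autocorrelation of the bin counts
    conv = np.correlate(cnt, cnt, mode="full")[nb - 1 :]
    paircnt = conv.copy()
    paircnt[0] = (conv[0] - cnt.sum()) / 2.0  # unordered same-bin pairs
    return dd, paircnt, cnt


_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _phi4_sum(n: int, dd: float, paircnt: np.ndarray, h: float) -> float:
    delta = np.arange(len(paircnt)) * dd / h
    keep = delta < 40.0
    delta = delta[keep]
    term = np.exp(-0.5 * delta**2) * (delta**4 - 6.0 * delta**2 + 3.0)
    s = 2.0 * float(term @ paircnt[keep]) + n * 3.0
    return s / (n * (n - 1) * h**5 * _SQRT_2PI)


def _phi6_sum(n: int, dd: float, paircnt: np.ndarray, h: float) -> float:
    delta = np.arange(len(paircnt)) * dd / h
    keep = delta < 40.0
    delta = delta[keep]
    term = np.exp(-0.5 * delta**2) * (delta**6 - 15.0 * delta**4 + 45.0 * delta**2 - 15.0)
    s = 2.0 * float(term @ paircnt[keep]) + n * (-15.0)
    return s / (n * (n - 1) * h**7 * _SQRT_2PI)


def sheather_jones_bandwidth(x: Sequence[float], nb: int = 1000) -> float:
    """Sheather-Jones solve-the-equation plug-in bandwidth for a Gaussian kernel.

    Solves h = [R(K) / (n * sigma_K^4 * SD(alpha_2(h)))]^(1/5) where SD is
    the binned plug-in estimate of the integrated squared density second
    derivative, following the classical solve-the-equation recipe (pair
    counts binned into ``nb`` bins).  Raises ValidationError when the
    required functionals are not estimable (e.g. near-degenerate data).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValidationError("need at least two observations for a bandwidth")
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        raise ValidationError("zero scale; all observations (nearly) identical")

    dd, paircnt, _ = _bin_pair_counts(x, nb=nb)
    a = 1.24 * scale * n ** (-1.0 / 7.0)
    b = 1.23 * scale * n ** (-1.0 / 9.0)
    c1 = 1.0 / (2.0 * np.sqrt(np.pi) * n)
    td = -_phi6_sum(n, dd, paircnt, b)
    if not np.isfinite(td) or td <= 0:
        raise ValidationError("sample too sparse to estimate the plug-in functional")
    sda = _phi4_sum(n, dd, paircnt, a)
    if not np.isfinite(sda) or sda <= 0:
        raise ValidationError("sample too sparse to estimate the plug-in functional")
    alph2 = 1.357 * (sda / td) ** (1.0 / 7.0)

    def f_sd(h: float) -> float:
        return (c1 / _phi4_sum(n, dd, paircnt, alph2 * h ** (5.0 / 7.0))) ** 0.2 - h

    hmax = 1.144 * scale * n ** (-0.2)
    lower, upper = 0.1 * hmax, hmax
    itry = 0
    while f_sd(lower) * f_sd(upper) > 0:
        itry += 1
        if itry > 99:
            raise ValidationError("no solution in the searched range of bandwidths")
        if itry % 2:
            upper *= 1.2
        else:
            lower /= 1.2
    return float(brentq(f_sd, lower, upper, xtol=0.1 * lower))


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        raise ValidationError("zero scale; all observations (nearly) identical")
    return 0.9 * scale * n ** (-0.2)


def estimate_density(
    distances: Sequence[float],
    window: int = 500_000,
    adjust: float = 8.0,
    min_count: int = 50,
    source: str = "",
) -> DistanceDensity:
    """Estimate the eQTL-TSS signed-distance density.

    Distances outside the +/- ``window`` are discarded.  The kernel is
    Gaussian with bandwidth ``adjust`` times the Sheather-Jones plug-in
    value (falling back to Silverman's rule, with a warning, if the
    plug-in solver fails), evaluated at 512 equally spaced points spanning
    exactly the data range — the analogue of a zero-cut density estimate,
    so no grid point falls beyond the observed distances.
    """
    d = np.asarray(distances, dtype=float)
    d = d[np.abs(d) <= window]
    if len(d) < min_count:
        raise ValidationError(
            f"only {len(d)} distances inside the +/-{window} bp window "
            f"(minimum {min_count}); pool additional eQTL records"
        )
    try:
        bw = sheather_jones_bandwidth(d)
    except ValidationError as exc:
        if "identical" in str(exc):
            raise
        warnings.warn(
            f"Sheather-Jones bandwidth failed ({exc}); falling back to Silverman's rule",
            stacklevel=2,
        )
        bw = _silverman_bandwidth(d)
    h = bw * adjust
    grid = np.linspace(d.min(), d.max(), DENSITY_GRID_SIZE)
    dens = _gaussian_kde_eval(d, grid, h)
    return DistanceDensity(
        grid=grid,
        density=dens,
        bandwidth=h,
        window=window,
        source=source,
        meta={"n": int(len(d)), "bw_unadjusted": float(bw), "adjust": float(adjust)},
    )


def _gaussian_kde_eval(data: np.ndarray, grid: np.ndarray, h: float, chunk: int = 2048) -> np.ndarray:
    out = np.zeros(len(grid))
    inv = 1.0 / (h * _SQRT_2PI * len(data))
    for lo in range(0, len(data), chunk):
        block = data[lo : lo + chunk]
        z = (grid[:, None] - block[None, :]) / h
        out += np.exp(-0.5 * z**2).sum(axis=1)
    return out * inv


def density_to_weights(
    density: DistanceDensity,
    positions: Sequence[int],
    tss: int,
    strand: str,
    variant_ids: Optional[Sequence[str]] = None,
) -> PriorWeights:
    """Evaluate a distance density at each variant's signed TSS distance.

    Linear interpolation between grid points; positions beyond the grid
    range take the nearer boundary value.  A small positive floor keeps
    the vector from being identically zero.
    """
    positions = np.asarray(positions, dtype=np.int64)
    d = np.array([signed_distance(int(p), tss, strand) for p in positions], dtype=float)
    w = np.interp(d, density.grid, density.density)
    w = np.maximum(w, DENSITY_WEIGHT_FLOOR)
    if variant_ids is None:
        variant_ids = [f"pos{p}" for p in positions]
    return PriorWeights(variant_ids=np.asarray(variant_ids, dtype=object), w=w)


def abc_to_weights(
    records: Sequence[AbcRecord],
    gene: str,
    variants: Sequence[Tuple[str, str, int]],
) -> PriorWeights:
    """ABC-score weights for ``variants`` (tuples of (id, chrom, 1-based pos)).

    Records are filtered to ``gene``; per enhancer interval the score is
    the median across biosamples; a variant inside an interval (0-based
    half-open test on pos-1) gets that score, taking the maximum when
    intervals overlap; a variant in no interval gets 0.0075.
    """
    by_interval: Dict[Tuple[str, int, int], List[float]] = {}
    for rec in records:
        if rec.gene_id == gene:
            by_interval.setdefault((rec.chrom, rec.start, rec.end), []).append(rec.score)
    medians = {key: float(np.median(scores)) for key, scores in by_interval.items()}

    ids, w = [], []
    for vid, chrom, pos in variants:
        pos0 = int(pos) - 1
        hits = [
            s
            for (c, start, end), s in medians.items()
            if c == chrom and start <= pos0 < end
        ]
        ids.append(vid)
        w.append(max(hits) if hits else ABC_MISSING_SCORE)
    return PriorWeights(variant_ids=np.asarray(ids, dtype=object), w=np.asarray(w))


def gnocchi_to_weights(
    records: Sequence[GnocchiRecord],
    variants: Sequence[Tuple[str, str, int]],
) -> PriorWeights:
    """Softmax-transformed constraint-score weights for a variant list.

    Each variant takes the score of the region containing it, or of the
    nearest scored region on its chromosome (interval-edge distance; ties
    broken towards the lower start coordinate).  The signed scores are
    then mapped through a max-subtracted softmax over the region's
    variants, so the weights sum to 1.
    """
    by_chrom: Dict[str, List[GnocchiRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda r: (r.start, r.end))

    ids, scores = [], []
    for vid, chrom, pos in variants:
        regions = by_chrom.get(chrom)
        if not regions:
            raise ValidationError(f"no constraint regions on chromosome {chrom!r}")
        pos0 = int(pos) - 1
        best, best_dist = None, None
        for reg in regions:
            if reg.start <= pos0 < reg.end:
                dist = 0
            elif pos0 < reg.start:
                dist = reg.start - pos0
            else:
                dist = pos0 - (reg.end - 1)
            if best_dist is None or dist < best_dist:
                best, best_dist = reg, dist
        ids.append(vid)
        scores.append(best.score)

    scores = np.asarray(scores, dtype=float)
    w = np.exp(scores - scores.max())
    w /= w.sum()
    return PriorWeights(variant_ids=np.asarray(ids, dtype=object), w=w)


def polyfun_to_weights(
    records: Sequence[PolyFunRecord],
    variants: Sequence[Tuple[str, str, int]],
) -> PriorWeights:
    """Per-SNP heritability weights; unmatched SNPs get the table minimum."""
    if not records:
        raise ValidationError("empty per-SNP variance table")
    by_snp = {rec.snp: rec.variance for rec in records if rec.snp is not None}
    by_pos = {(rec.chrom, rec.pos): rec.variance for rec in records}
    floor = min(rec.variance for rec in records)

    ids, w = [], []
    for vid, chrom, pos in variants:
        if vid in by_snp:
            var = by_snp[vid]
        elif (chrom, int(pos)) in by_pos:
            var = by_pos[(chrom, int(pos))]
        else:
            var = floor
        ids.append(vid)
        w.append(var)
    w = np.asarray(w, dtype=float)
    if not np.any(w > 0):
        # every matched variance is zero: fall back to a flat vector
        w = np.ones_like(w)
    return PriorWeights(variant_ids=np.asarray(ids, dtype=object), w=w)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    for col in cols:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")


def read_eqtl_table(path) -> List[EqtlRecord]:
    """Read a significant-eQTL table: ``gene snp chrom pos tss strand p``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "snp": str, "chrom": str})
    _require_columns(df, ["gene", "pos", "tss", "strand", "p"], path)
    return [
        EqtlRecord(
            gene_id=row.gene,
            variant_pos=int(row.pos),
            tss=int(row.tss),
            strand=row.strand,
            p_value=float(row.p),
            variant_id=getattr(row, "snp", None),
        )
        for row in df.itertuples(index=False)
    ]


def read_abc_table(path) -> List[AbcRecord]:
    """Read an enhancer-gene link table: ``chrom start end gene biosample score``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str, "biosample": str})
    _require_columns(df, ["chrom", "start", "end", "gene", "biosample", "score"], path)
    return [
        AbcRecord(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            gene_id=row.gene,
            biosample=row.biosample,
            score=float(row.score),
        )
        for row in df.itertuples(index=False)
    ]


def read_gnocchi_table(path) -> List[GnocchiRecord]:
    """Read a constraint-score table: ``chrom start end score``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["chrom", "start", "end", "score"], path)
    return [
        GnocchiRecord(chrom=row.chrom, start=int(row.start), end=int(row.end), score=float(row.score))
        for row in df.itertuples(index=False)
    ]


def read_polyfun_table(path) -> List[PolyFunRecord]:
    """Read a per-SNP variance table: ``chrom pos snp variance``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp": str})
    _require_columns(df, ["chrom", "pos", "variance"], path)
    return [
        PolyFunRecord(
            chrom=row.chrom,
            pos=int(row.pos),
            variance=float(row.variance),
            snp=getattr(row, "snp", None),
        )
        for row in df.itertuples(index=False)
    ]


def write_density(density: DistanceDensity, tsv_path, json_path=None) -> None:
    """Write a density as a 512-row ``distance density`` TSV + JSON sidecar."""
    pd.DataFrame({"distance": density.grid, "density": density.density}).to_csv(
        tsv_path, sep="\t", index=False, float_format="%.12g"
    )
    if json_path is not None:
        sidecar = {
            "bandwidth": density.bandwidth,
            "window": density.window,
            "source": density.source,
            "meta": density.meta,
        }
        with open(json_path, "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_density(tsv_path, json_path=None) -> DistanceDensity:
    """Read a density written by :func:`write_density`."""
    df = pd.read_csv(tsv_path, sep="\t")
    _require_columns(df, ["distance", "density"], tsv_path)
    bandwidth, window, source, meta = 1.0, 500_000, "", {}
    if json_path is not None:
        with open(json_path) as fh:
            sidecar = json.load(fh)
        bandwidth = sidecar.get("bandwidth", bandwidth)
        window = sidecar.get("window", window)
        source = sidecar.get("source", source)
        meta = sidecar.get("meta", meta)
    return DistanceDensity(
        grid=df["distance"].to_numpy(dtype=float),
        density=df["density"].to_numpy(dtype=float),
        bandwidth=bandwidth,
        window=window,
        source=source,
        meta=meta,
    )
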