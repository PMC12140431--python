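"""Benchmark metrics for colocalisation calls.

Evaluates prior-specification strategies against ground-truth pQTL-eQTL
style call sets: a call between a query gene (e.g. the protein's gene) and
a target gene (the eQTL gene) is *significant* when its posterior
probability of a shared causal variant exceeds a threshold (0.8 by
convention, strict inequality).  A significant same-gene call is a true
positive, a significant different-gene call a false positive, and so on;
recall/precision and a ROC-style sweep over thresholds 0.5, 0.55, ..., 0.95
summarise performance.  Also provides the iterative 1 Mb peak-merging
heuristic used to define GWAS loci, and a report of loci whose
significance status changes between a uniform-prior and a weighted run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ColocCall",
    "ConfusionCounts",
    "Peak",
    "aggregate_max",
    "classify",
    "recall_precision",
    "roc_sweep",
    "merge_peaks",
    "significance_change_report",
    "DEFAULT_THRESHOLDS",
    "SIGNIFICANCE_THRESHOLD",
]

#: Conventional significance threshold: a colocalisation is called when
#: Pr(H4) exceeds this value (strict inequality).
SIGNIFICANCE_THRESHOLD = 0.8

#: Threshold grid for the ROC-style sweep.
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass(frozen=True)
class ColocCall:
    """One colocalisation result between a query gene and a target gene."""

    query_gene: str
    target_gene: str
    dataset: str
    pp_h4: float

    def __post_init__(self):
        if not 0.0 <= self.pp_h4 <= 1.0:
            raise ValueError(f"pp_h4 must lie in [0, 1], got {self.pp_h4}")

    @property
    def same_gene(self) -> bool:
        return self.query_gene == self.target_gene


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN counts at a fixed significance threshold."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def aggregate_max(calls: Iterable[ColocCall]) -> Dict[Tuple[str, str], float]:
    """Maximum pp_h4 per (query_gene, target_gene) pair across datasets.

    A pair colocalises if it colocalises in *any* dataset, so the pair's
    evidence is its best posterior across datasets.
    """
    out: Dict[Tuple[str, str], float] = {}
    for call in calls:
        key = (call.query_gene, call.target_gene)
        if key not in out or call.pp_h4 > out[key]:
            out[key] = call.pp_h4
    return out


def classify(
    aggregated: Mapping[Tuple[str, str], float],
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> ConfusionCounts:
    """Confusion counts over aggregated gene pairs at one threshold.

    Same-gene pairs above the threshold are true positives; same-gene
    pairs below are false negatives; different-gene pairs above/below are
    false/true negatives respectively.  The comparison is strict
    (pp_h4 > threshold), matching the conventional "Pr(H4) > 0.8" rule.
    """
    tp = fp = fn = tn = 0
    for (query, target), pp in aggregated.items():
        significant = pp > threshold
        if query == target:
            if significant:
                tp += 1
            else:
                fn += 1
        else:
            if significant:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def recall_precision(c: ConfusionCounts) -> Tuple[float, float]:
    """(recall, precision) = (TP/(TP+FN), TP/(TP+FP)); NaN when undefined."""
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else math.nan
    return recall, precision


def roc_sweep(
    aggregated: Mapping[Tuple[str, str], float],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> List[Tuple[float, float, float]]:
    """(threshold, TPR, FPR) rows over a grid of significance thresholds.

    TPR = TP/(TP+FN) and FPR = FP/(FP+TN); both are non-increasing in the
    threshold because raising it can only demote calls.  Undefined rates
    are reported as NaN.
    """
    rows = []
    for t in thresholds:
        c = classify(aggregated, threshold=t)
        tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
        fpr = c.fp / (c.fp + c.tn) if (c.fp + c.tn) > 0 else math.nan
        rows.append((float(t), tpr, fpr))
    return rows


@dataclass(frozen=True)
class Peak:
    """A genome-wide-significant lead variant (position and p-value)."""

    position: int
    p_value: float

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")


def merge_peaks(
    peaks: Sequence[Peak],
    window: int = 1_000_000,
    rounds: int = 5,
) -> List[Peak]:
    """Iteratively merge association peaks within ``window`` bp.

    In each of ``rounds`` rounds, peaks are visited in order of increasing
    p-value; each surviving peak absorbs every remaining peak within
    ``window`` of it, keeping the more significant lead's position.  After
    the rounds the retained peaks are returned sorted by position.
    """
    current = list(peaks)
    for _ in range(rounds):
        current.sort(key=lambda pk: (pk.p_value, pk.position))
        kept: List[Peak] = []
        consumed = [False] * len(current)
        for i, pk in enumerate(current):
            if consumed[i]:
                continue
            for j in range(i + 1, len(current)):
                if not consumed[j] and abs(current[j].position - pk.position) <= window:
                    consumed[j] = True
            kept.append(pk)
        if len(kept) == len(current):
            current = kept
            break
        current = kept
    return sorted(current, key=lambda pk: pk.position)


@dataclass(frozen=True)
class SignificanceChangeReport:
    """Loci crossing the significance threshold between two runs."""

    n_considered: int
    gained: Tuple[str, ...]
    lost: Tuple[str, ...]

    @property
    def n_changed(self) -> int:
        return len(self.gained) + len(self.lost)

    @property
    def fraction_changed(self) -> float:
        return self.n_changed / self.n_considered if self.n_considered else math.nan


def significance_change_report(
    results_uniform: Mapping[str, float],
    results_weighted: Mapping[str, float],
    threshold: float = SIGNIFICANCE_THRESHOLD,
    floor: float = 0.5,
) -> SignificanceChangeReport:
    """Compare uniform-prior and weighted Pr(H4) values locus by locus.

    Only loci with some evidence of colocalisation in either run
    (max of the two values > ``floor``) are considered.  A locus is
    *gained* when the weighted run crosses above the threshold and
    *lost* when it crosses below; the fraction changed is reported over
    the considered loci.
    """
    if set(results_uniform) != set(results_weighted):
        only_u = sorted(set(results_uniform) - set(results_weighted))
        only_w = sorted(set(results_weighted) - set(results_uniform))
        raise KeyError(f"result sets keyed differently: {only_u or only_w}")
    gained, lost = [], []
    n_considered = 0
    for locus in sorted(results_uniform):
        u, w = results_uniform[locus], results_weighted[locus]
        if max(u, w) <= floor:
            continue
        n_considered += 1
        sig_u, sig_w = u > threshold, w > threshold
        if sig_w and not sig_u:
            gained.append(locus)
        elif sig_u and not sig_w:
            lost.append(locus)
    return SignificanceChangeReport(
        n_considered=n_considered, gained=tuple(gained), lost=tuple(lost)
    )
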