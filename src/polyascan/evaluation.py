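"""Classification metrics, rank AUC, tolerant site overlap, and PFM export.

Everything metric-shaped in the pipeline derives from integer confusion
counts, so extreme-imbalance settings (one cleavage site per ~4500 genomic
positions) report exactly, with enrichment = precision / prevalence giving
the fold improvement over random position calling.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genome_io import GenomicInterval
from .pas_scanner import CandidateSite

_BASE_ROWS = "ACGT"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Fractions in [0, 1]; a ratio with zero denominator is ``None``."""

    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    specificity: Optional[float]
    prevalence: Optional[float]
    enrichment: Optional[float]


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def confusion_metrics(c: ConfusionCounts) -> MetricReport:
    """Standard binary metrics from confusion counts.

    ``enrichment`` is precision divided by prevalence: how many-fold better
    than calling positions at random.
    """
    if c.total == 0:
        raise ValueError("all-zero confusion counts")
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    if precision is None or recall is None:
        f1 = None
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    prevalence = _ratio(c.tp + c.fn, c.total)
    enrichment = (
        precision / prevalence
        if precision is not None and prevalence
        else None
    )
    return MetricReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=_ratio(c.tn, c.tn + c.fp),
        prevalence=prevalence,
        enrichment=enrichment,
    )


def percent(x: float, decimals: int) -> float:
    """x as a percentage rounded (half-even) to the given decimals."""
    return round(100.0 * x, decimals)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC by the Mann-Whitney rank formula with midrank tie handling.

    Equals the fraction of (positive, negative) pairs the positive wins,
    counting ties as half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    pos_rank_sum = float(ranks[labels == 1].sum())
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def overlap_fraction(
    predicted: Sequence[CandidateSite],
    reference: Sequence[GenomicInterval],
    tol: int,
) -> float:
    """Fraction of predictions within ``tol`` nt of some reference site.

    Boundary inclusive: ``|pos - ref| <= tol`` counts. Matching is
    strand-aware only when both records carry a strand; reference positions
    are interval starts (1-bp cleavage records). Sorted-array bisection per
    chromosome keeps this O((n+m) log m).
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if not predicted or not reference:
        raise ValueError("both site lists must be non-empty")
    stranded: dict[tuple[str, str], list[int]] = {}
    unstranded: dict[str, list[int]] = {}
    for r in reference:
        if r.strand is None:
            unstranded.setdefault(r.chrom, []).append(r.start)
        else:
            stranded.setdefault((r.chrom, r.strand), []).append(r.start)
    for arr in stranded.values():
        arr.sort()
    for arr in unstranded.values():
        arr.sort()

    def near(arr: list[int], pos: int) -> bool:
        i = bisect_left(arr, pos - tol)
        return i < len(arr) and arr[i] <= pos + tol

    hits = 0
    for p in predicted:
        ok = near(unstranded.get(p.chrom, []), p.pos)
        if not ok:
            ok = near(stranded.get((p.chrom, p.strand), []), p.pos)
        hits += ok
    return hits / len(predicted)


@dataclass
class PositionFrequencyMatrix:
    """Base counts per window column (rows A, C, G, T)."""

    counts: np.ndarray
    n_sequences: int
    n_excluded: int = 0

    @property
    def length(self) -> int:
        return self.counts.shape[1]


def build_pfm(windows: Sequence[str]) -> PositionFrequencyMatrix:
    """Count bases per column over equal-length windows.

    Sequences containing ``N`` are excluded (and counted), so every column
    sums to the number of retained sequences.
    """
    if not windows:
        raise ValueError("need at least one window")
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ValueError("windows must all have equal length")
    counts = np.zeros((4, length), dtype=int)
    excluded = 0
    kept = 0
    for w in windows:
        if "N" in w:
            excluded += 1
            continue
        kept += 1
        for j, b in enumerate(w):
            counts[_BASE_ROWS.index(b), j] += 1
    if kept == 0:
        raise ValueError("every window contained N; nothing to count")
    return PositionFrequencyMatrix(counts, kept, excluded)


def information_content(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Per-column information in bits: 2 minus the Shannon entropy."""
    freqs = pfm.counts / pfm.counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    return 2.0 + plogp.sum(axis=0)


def write_pfm(pfm: PositionFrequencyMatrix, path: str | Path) -> pd.DataFrame:
    """Export the 4 x L count matrix (plus information row) as TSV."""
    df = pd.DataFrame(pfm.counts, index=list(_BASE_ROWS))
    df.loc["information_bits"] = information_content(pfm)
    df.to_csv(path, sep="\t")
    return df
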