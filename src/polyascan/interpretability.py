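"""Model-interpretability probes: PAS perturbation and attention analysis.

The perturbation experiment replaces canonical PAS occurrences (AATAAA,
ATTAAA) in positive windows with random hexamers at increasing rates
p = 10%..100% and records how a sequence scorer's confidence and
misprediction count respond — a model that truly relies on the signal
degrades progressively.

The attention probe tokenizes each sequence into k-mers, ranks tokens by
attention received (column mean of a provider-supplied, head-averaged
token x token matrix), and aggregates the top-attended k-mers over samples.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pas_scanner import CANONICAL_MOTIFS, SequenceScorer

DEFAULT_LEVELS = tuple(round(0.1 * i, 1) for i in range(1, 11))


@dataclass(frozen=True)
class PerturbationConfig:
    levels: tuple[float, ...] = DEFAULT_LEVELS
    motifs: tuple[str, ...] = CANONICAL_MOTIFS
    seed: int = 0
    allow_identity: bool = False

    def __post_init__(self) -> None:
        if any(not 0.0 <= p <= 1.0 for p in self.levels):
            raise ValueError("levels must lie in [0, 1]")
        if any(len(m) != 6 for m in self.motifs):
            raise ValueError("motifs must be hexamers")


@dataclass
class PerturbationResult:
    level: float
    probabilities: np.ndarray
    n_total: int

    @property
    def n_mispred(self) -> int:
        """Positives the scorer no longer calls (strictly below 0.5)."""
        return int(np.sum(self.probabilities < 0.5))


def find_motif_occurrences(
    seq: str, motifs: Sequence[str] = CANONICAL_MOTIFS
) -> list[int]:
    """Start indices of motif occurrences, greedy left-to-right, no overlap."""
    motif_set = frozenset(motifs)
    width = len(next(iter(motif_set)))
    hits: list[int] = []
    i = 0
    while i <= len(seq) - width:
        if seq[i : i + width] in motif_set:
            hits.append(i)
            i += width
        else:
            i += 1
    return hits


def _random_replacement(
    motif: str, rng: np.random.Generator, allow_identity: bool
) -> str:
    while True:
        r = "".join(rng.choice(list("ACGT"), size=len(motif)))
        if allow_identity or r != motif:
            return r


def perturb_sequence(
    seq: str,
    level: float,
    motifs: Sequence[str] = CANONICAL_MOTIFS,
    rng: Optional[np.random.Generator] = None,
    allow_identity: bool = False,
) -> str:
    """Replace each motif occurrence with a random hexamer w.p. ``level``.

    The Bernoulli gate is drawn independently per occurrence. By default the
    replacement is resampled if it equals the original motif, so level 1
    guarantees no matched occurrence survives; ``allow_identity`` restores
    the plain uniform draw. Length and all bases outside matched spans are
    untouched; level 0 is the identity.
    """
    if rng is None:
        rng = np.random.default_rng()
    chars = list(seq)
    for start in find_motif_occurrences(seq, motifs):
        if rng.random() <= level and level > 0.0:
            motif = seq[start : start + 6]
            chars[start : start + 6] = _random_replacement(
                motif, rng, allow_identity
            )
    return "".join(chars)


def perturbation_curve(
    windows: Sequence[str],
    scorer: SequenceScorer,
    config: PerturbationConfig = PerturbationConfig(),
) -> list[PerturbationResult]:
    """Score every window at every perturbation level.

    One uniform variate ``r`` is drawn per motif occurrence and compared
    against each level (common random numbers), so the occurrences
    perturbed at level p are a subset of those perturbed at any higher
    level; the per-occurrence replacement hexamer is likewise shared. All
    windows count toward ``n_total`` at every level, whether or not any of
    their motifs were touched.
    """
    if not windows:
        raise ValueError("need at least one window")
    rng = np.random.default_rng(config.seed)
    plans = []  # per window: list of (start, r, replacement)
    for seq in windows:
        plan = []
        for start in find_motif_occurrences(seq, config.motifs):
            r = rng.random()
            repl = _random_replacement(
                seq[start : start + 6], rng, config.allow_identity
            )
            plan.append((start, r, repl))
        plans.append(plan)

    results = []
    for level in config.levels:
        probs = np.empty(len(windows))
        for i, seq in enumerate(windows):
            chars = list(seq)
            for start, r, repl in plans[i]:
                if level > 0.0 and r <= level:
                    chars[start : start + 6] = repl
            probs[i] = scorer("".join(chars))
        results.append(PerturbationResult(level, probs, len(windows)))
    return results


def export_perturbation_tsv(
    results: Sequence[PerturbationResult], probs_path: str | Path,
    counts_path: str | Path,
) -> None:
    """Per-level probability distributions and misprediction counts as TSV."""
    rows = [
        {"level": res.level, "sample": i, "probability": p}
        for res in results
        for i, p in enumerate(res.probabilities)
    ]
    pd.DataFrame(rows).to_csv(probs_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {"level": r.level, "n_mispred": r.n_mispred, "n_total": r.n_total}
            for r in results
        ]
    ).to_csv(counts_path, sep="\t", index=False)


@dataclass
class AttentionSummary:
    """Frequencies of k-mers among the top-attended tokens across samples."""

    kmer_counts: Counter = field(default_factory=Counter)
    top_k: int = 1
    n_samples: int = 0

    def most_common(self, n: int = 20) -> list[tuple[str, int]]:
        return self.kmer_counts.most_common(n)


def top_attended_kmers(
    attentions: Sequence[np.ndarray],
    seqs: Sequence[str],
    kmer: int = 6,
    top_k: int = 1,
) -> AttentionSummary:
    """Aggregate the top-attended k-mer tokens over samples.

    Token attention received is the column mean of the attention matrix
    (average over query positions). Ties go to the leftmost token. Each
    matrix must be n_tokens x n_tokens for its sequence's non-overlapping
    k-mer tokenization.
    """
    if len(attentions) != len(seqs):
        raise ValueError("attentions and seqs must align 1:1")
    if top_k <= 0 or kmer <= 0:
        raise ValueError("kmer and top_k must be positive")
    summary = AttentionSummary(top_k=top_k)
    for mat, seq in zip(attentions, seqs):
        mat = np.asarray(mat, dtype=float)
        n_tokens = len(seq) // kmer
        if mat.shape != (n_tokens, n_tokens):
            raise ValueError(
                f"attention shape {mat.shape} does not match "
                f"{n_tokens} tokens of a {len(seq)}-nt sequence"
            )
        received = mat.mean(axis=0)
        # Stable sort on negated scores: equal scores keep left-to-right order.
        order = np.argsort(-received, kind="stable")[: min(top_k, n_tokens)]
        for tok in order:
            summary.kmer_counts[seq[tok * kmer : (tok + 1) * kmer]] += 1
        summary.n_samples += 1
    return summary


def export_kmer_frequencies(
    summary: AttentionSummary, path: str | Path
) -> pd.DataFrame:
    df = pd.DataFrame(
        summary.kmer_counts.most_common(), columns=["kmer", "count"]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
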