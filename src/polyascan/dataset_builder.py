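"""Construction of balanced poly(A)-site classification datasets.

Positives are 101-nt windows around annotated cleavage sites with the
cleavage base (index 50, the biological 51st nucleotide) forced to ``A``.
Negatives are PAS-bearing hard negatives: windows from genic or intergenic
regions with a reference ``A`` at index 50 and a canonical hexamer (AATAAA or
ATTAAA) starting 10-35 nt upstream, excluding anything whose window overlaps
an annotated site. The two sourcing regimes give the gene-gene and
gene-intergene datasets. Splitting is stratified 5-fold rotation:
3 folds train / 1 validation / 1 test = 60/20/20.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import Genome, GenomicInterval, reverse_complement
from .pas_scanner import (
    CANONICAL_MOTIFS,
    CLEAVAGE_INDEX,
    MAX_PAS_DISTANCE,
    MIN_PAS_DISTANCE,
    WINDOW,
)

logger = logging.getLogger(__name__)

FLANK = CLEAVAGE_INDEX  # 50 nt each side of the cleavage base


@dataclass(frozen=True)
class SequenceWindow:
    """One labeled 101-nt training window."""

    seq: str
    label: int
    origin: GenomicInterval
    dataset: str = "gene_gene"
    cleavage_index: int = CLEAVAGE_INDEX

    def __post_init__(self) -> None:
        if len(self.seq) != WINDOW:
            raise ValueError(f"window must be {WINDOW} nt, got {len(self.seq)}")
        if self.seq[self.cleavage_index] != "A":
            raise ValueError("cleavage base must be A")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class FoldSplit:
    fold_id: int
    train: list[SequenceWindow]
    val: list[SequenceWindow]
    test: list[SequenceWindow]


def build_positives(
    genome: Genome,
    polya_sites: Sequence[GenomicInterval],
    dataset: str = "gene_gene",
) -> list[SequenceWindow]:
    """One positive window per cleavage site that fits its chromosome.

    The base at index 50 is overwritten to ``A`` regardless of the reference
    (minus-strand sites are reverse-complemented into cleavage orientation
    first). Boundary sites that cannot host a full window are skipped and
    counted in the log.
    """
    windows: list[SequenceWindow] = []
    skipped = 0
    for site in polya_sites:
        seq = genome[site.chrom]
        pos = site.start
        if pos - FLANK < 0 or pos + FLANK + 1 > len(seq):
            skipped += 1
            continue
        window = seq[pos - FLANK : pos + FLANK + 1]
        if site.strand == "-":
            window = reverse_complement(window)
        window = window[:CLEAVAGE_INDEX] + "A" + window[CLEAVAGE_INDEX + 1 :]
        windows.append(SequenceWindow(window, 1, site, dataset))
    if skipped:
        logger.info("build_positives: skipped %d boundary sites", skipped)
    return windows


def _negative_rule_ok(window: str) -> bool:
    """Reference A at index 50 plus a canonical PAS starting in the band."""
    if window[CLEAVAGE_INDEX] != "A":
        return False
    lo = CLEAVAGE_INDEX - MAX_PAS_DISTANCE
    hi = CLEAVAGE_INDEX - MIN_PAS_DISTANCE
    return any(
        window[s : s + 6] in CANONICAL_MOTIFS for s in range(lo, hi + 1)
    )


def enumerate_negative_loci(
    genome: Genome,
    polya_sites: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """All cleavage positions in ``regions`` qualifying as hard negatives.

    A locus qualifies when its full 101-nt window lies inside one region,
    the reference base at the locus is ``A``, a canonical PAS starts
    10-35 nt upstream, and the window overlaps no annotated poly(A) site.
    """
    motif_re = re.compile("|".join(f"(?={m})" for m in CANONICAL_MOTIFS))
    sites_by_chrom: dict[str, list[GenomicInterval]] = {}
    for s in polya_sites:
        sites_by_chrom.setdefault(s.chrom, []).append(s)

    loci: list[GenomicInterval] = []
    seen: set[tuple[str, int]] = set()
    for region in regions:
        seq = genome[region.chrom]
        lo = max(region.start + FLANK, FLANK)
        hi = min(region.end - FLANK - 1, len(seq) - FLANK - 1)
        if hi < lo:
            continue
        # Motif-first enumeration: each occurrence licenses cleavage
        # positions 10-35 nt downstream of its start.
        span_lo = max(0, lo - MAX_PAS_DISTANCE)
        for m in motif_re.finditer(seq, span_lo, hi + 1):
            mstart = m.start()
            for pos in range(mstart + MIN_PAS_DISTANCE, mstart + MAX_PAS_DISTANCE + 1):
                if pos < lo or pos > hi or seq[pos] != "A":
                    continue
                if (region.chrom, pos) in seen:
                    continue
                window_iv = GenomicInterval(
                    region.chrom, pos - FLANK, pos + FLANK + 1
                )
                if any(
                    window_iv.overlaps(s)
                    for s in sites_by_chrom.get(region.chrom, [])
                ):
                    continue
                seen.add((region.chrom, pos))
                loci.append(GenomicInterval(region.chrom, pos, pos + 1, strand="+"))
    loci.sort(key=lambda iv: (iv.chrom, iv.start))
    return loci


def build_negatives(
    genome: Genome,
    polya_sites: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
    mode: Literal["genic", "intergenic"],
    n: int,
    seed: int = 0,
) -> list[SequenceWindow]:
    """Sample ``n`` hard-negative windows from genic or intergenic space.

    ``regions`` is always the gene annotation; in intergenic mode the
    complement over each chromosome is searched instead. Sampling is
    uniform without replacement over all qualifying loci, seeded. Raises
    if fewer than ``n`` loci qualify, naming the shortfall.
    """
    if mode not in ("genic", "intergenic"):
        raise ValueError(f"unknown mode {mode!r}")
    search = (
        list(regions)
        if mode == "genic"
        else _complement_regions(genome, regions)
    )
    if not search:
        raise ValueError(f"no {mode} regions to sample from")
    loci = enumerate_negative_loci(genome, polya_sites, search)
    if len(loci) < n:
        raise ValueError(
            f"only {len(loci)} qualifying negative loci in {mode} regions, "
            f"need {n} (short by {n - len(loci)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(loci), size=n, replace=False) if n else []
    dataset = "gene_gene" if mode == "genic" else "gene_intergene"
    out = []
    for i in sorted(int(c) for c in chosen):
        locus = loci[i]
        seq = genome[locus.chrom]
        window = seq[locus.start - FLANK : locus.start + FLANK + 1]
        assert _negative_rule_ok(window)
        out.append(SequenceWindow(window, 0, locus, dataset))
    return out


def _complement_regions(
    genome: Genome, regions: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out = []
    for chrom in genome.chroms:
        cursor = 0
        for r in sorted(by_chrom.get(chrom, []), key=lambda r: r.start):
            if r.start > cursor:
                out.append(GenomicInterval(chrom, cursor, r.start))
            cursor = max(cursor, r.end)
        if cursor < genome.length(chrom):
            out.append(GenomicInterval(chrom, cursor, genome.length(chrom)))
    return out


def balance_and_split(
    pos: Sequence[SequenceWindow],
    neg: Sequence[SequenceWindow],
    n_folds: int = 5,
    seed: int = 0,
) -> list[FoldSplit]:
    """Downsample to class balance, then build rotating stratified folds.

    Each class is shuffled and cut into ``n_folds`` near-equal chunks; fold
    ``i`` takes chunk ``i`` as test, chunk ``i+1 (mod n_folds)`` as
    validation and the rest as training — with 5 folds that is the 60/20/20
    protocol. The union of test sets over folds covers every window once.
    """
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)
    k = min(len(pos), len(neg))
    pos = [pos[i] for i in rng.permutation(len(pos))[:k]]
    neg = [neg[i] for i in rng.permutation(len(neg))[:k]]

    pos_chunks = [list(c) for c in np.array_split(np.arange(k), n_folds)]
    neg_chunks = [list(c) for c in np.array_split(np.arange(k), n_folds)]

    folds: list[FoldSplit] = []
    for f in range(n_folds):
        test_ids = {f}
        val_ids = {(f + 1) % n_folds}
        train_ids = set(range(n_folds)) - test_ids - val_ids

        def gather(ids: set[int]) -> list[SequenceWindow]:
            out: list[SequenceWindow] = []
            for c in sorted(ids):
                out.extend(pos[i] for i in pos_chunks[c])
                out.extend(neg[i] for i in neg_chunks[c])
            return out

        folds.append(
            FoldSplit(f, gather(train_ids), gather(val_ids), gather(test_ids))
        )
    return folds


def dataset_table(windows: Sequence[SequenceWindow]) -> pd.DataFrame:
    """Flatten windows into the TSV interchange layout."""
    return pd.DataFrame(
        {
            "sequence": [w.seq for w in windows],
            "label": [w.label for w in windows],
            "chrom": [w.origin.chrom for w in windows],
            "pos": [w.origin.start for w in windows],
            "strand": [w.origin.strand or "." for w in windows],
            "dataset": [w.dataset for w in windows],
        }
    )


def write_dataset(
    folds: Sequence[FoldSplit], path: str | Path
) -> pd.DataFrame:
    frames = []
    for fold in folds:
        for part, windows in (
            ("train", fold.train),
            ("val", fold.val),
            ("test", fold.test),
        ):
            df = dataset_table(windows)
            df["fold"] = fold.fold_id
            df["split"] = part
            frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(path, sep="\t", index=False)
    return table
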