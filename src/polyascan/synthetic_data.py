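"""Synthetic genomes with planted poly(A) architecture, plus toy model stand-ins.

The generator emulates the sequence features the pipeline keys on:

* functional sites: cleavage adenine with ``C``/``G`` immediately 5', a
  canonical PAS hexamer (AATAAA or ATTAAA, ~70/30) starting 10-35 nt
  upstream, and a T/G-rich downstream sequence element (DSE) — the element
  real 3'-end machinery requires and the discriminative context signal here;
* decoy sites: the identical PAS arrangement but *no* DSE. Decoys pass the
  full Stage-1 sequence filter and are the hard negatives: PAS presence is
  necessary but not sufficient for functionality;
* i.i.d. background at configurable GC content, so chance PAS matches occur
  at realistic rates.

``toy_embedder``, ``toy_scorer`` and ``toy_attention`` are deterministic
stand-ins for a genome language model's mean-pooled embeddings, sequence
probability head, and final-layer attention. They carry just enough signal
(composition + DSE context, PAS-boosted attention) for the downstream
classification and interpretability machinery to be exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import Genome, GenomicInterval, write_bed, write_fasta
from .pas_scanner import CANONICAL_MOTIFS, CLEAVAGE_INDEX, WINDOW

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

#: Minimum center-to-center spacing between planted sites; anything above
#: 100 nt guarantees their 101-nt windows never overlap.
_MIN_SEPARATION = 110
_GRID_STEP = 130
_JITTER = 10
_EDGE_MARGIN = 51  # keeps every planted window fully inside its region

# Downstream element composition (A, C, G, T) for functional sites, placed
# +5..+29 relative to cleavage: strongly T/G-rich, as in real DSEs.
_DSE_PROBS = (0.10, 0.05, 0.30, 0.55)
_DSE_SPAN = (5, 30)


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    n_chroms: int = 2
    chrom_length: int = 50_000
    n_true_sites: int = 40
    n_decoy_sites: int = 40
    genic_fraction: float = 0.5
    pas_distance_range: tuple[int, int] = (10, 35)
    gc_content: float = 0.41
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.genic_fraction <= 1.0:
            raise ValueError("genic_fraction must be in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        lo, hi = self.pas_distance_range
        if not 10 <= lo <= hi <= 35:
            raise ValueError("pas_distance_range must lie within [10, 35]")
        if self.chrom_length < 4 * _EDGE_MARGIN:
            raise ValueError("chrom_length too small to hold any window")


@dataclass
class SyntheticGenomeBundle:
    genome: Genome
    polya_sites: list[GenomicInterval]
    gene_regions: list[GenomicInterval]
    decoy_sites: list[GenomicInterval]
    config: SyntheticGenomeConfig = field(
        default_factory=SyntheticGenomeConfig
    )

    def intergenic_regions(self) -> list[GenomicInterval]:
        """Complement of the gene regions over each chromosome."""
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for g in self.gene_regions:
            by_chrom.setdefault(g.chrom, []).append(g)
        out = []
        for chrom in self.genome.chroms:
            cursor = 0
            for g in sorted(by_chrom.get(chrom, []), key=lambda g: g.start):
                if g.start > cursor:
                    out.append(GenomicInterval(chrom, cursor, g.start))
                cursor = max(cursor, g.end)
            length = self.genome.length(chrom)
            if cursor < length:
                out.append(GenomicInterval(chrom, cursor, length))
        return out


def _distribute(total: int, buckets: int) -> list[int]:
    base, extra = divmod(total, buckets)
    return [base + (1 if i < extra else 0) for i in range(buckets)]


def _place_positions(
    region: GenomicInterval, k: int, rng: np.random.Generator
) -> list[int]:
    """k well-separated cleavage positions whose windows fit inside region."""
    if k == 0:
        return []
    lo = region.start + _EDGE_MARGIN + _JITTER
    hi = region.end - _EDGE_MARGIN - _JITTER
    grid = np.arange(lo, hi, _GRID_STEP)
    if len(grid) < k:
        raise ValueError(
            f"infeasible packing: {k} sites requested but only {len(grid)} "
            f"slots fit in {region.chrom}:{region.start}-{region.end}"
        )
    chosen = rng.choice(grid, size=k, replace=False)
    jitter = rng.integers(-_JITTER, _JITTER + 1, size=k)
    return sorted(int(p) for p in chosen + jitter)


def _plant_site(
    seq: np.ndarray,
    pos: int,
    functional: bool,
    distance_range: tuple[int, int],
    rng: np.random.Generator,
) -> None:
    motif = CANONICAL_MOTIFS[0] if rng.random() < 0.7 else CANONICAL_MOTIFS[1]
    d = int(rng.integers(distance_range[0], distance_range[1] + 1))
    seq[pos - d : pos - d + 6] = list(motif)
    seq[pos - 1] = "C" if rng.random() < 0.5 else "G"
    seq[pos] = "A"
    if functional:
        lo, hi = _DSE_SPAN
        seq[pos + lo : pos + hi] = rng.choice(
            _BASES, size=hi - lo, p=_DSE_PROBS
        )


def generate_genome(config: SyntheticGenomeConfig) -> SyntheticGenomeBundle:
    """Generate a seeded genome bundle with planted functional and decoy sites.

    Each chromosome carries one central gene region covering
    ``genic_fraction`` of its length. Functional sites go into gene regions;
    decoys are split evenly between genic and intergenic space so that both
    negative-sampling regimes see hard negatives. All planted counts match
    the config exactly; overlap-free placement is guaranteed by a spaced
    grid, and an infeasible request raises.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    n_genic_decoys = config.n_decoy_sites // 2
    n_inter_decoys = config.n_decoy_sites - n_genic_decoys
    true_per_chrom = _distribute(config.n_true_sites, config.n_chroms)
    gdecoy_per_chrom = _distribute(n_genic_decoys, config.n_chroms)
    idecoy_per_chrom = _distribute(n_inter_decoys, config.n_chroms)

    sequences: dict[str, str] = {}
    polya_sites: list[GenomicInterval] = []
    gene_regions: list[GenomicInterval] = []
    decoy_sites: list[GenomicInterval] = []

    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        length = config.chrom_length
        seq = rng.choice(_BASES, size=length, p=base_probs)

        gene_len = round(config.genic_fraction * length)
        gstart = (length - gene_len) // 2
        gene = GenomicInterval(chrom, gstart, gstart + gene_len) if gene_len else None
        if gene is not None:
            gene_regions.append(gene)

        # Genic placements: functional sites and genic decoys share one grid
        # so spacing holds between all of them.
        n_true, n_gdec = true_per_chrom[ci], gdecoy_per_chrom[ci]
        if n_true + n_gdec > 0:
            if gene is None:
                raise ValueError("genic sites requested with genic_fraction=0")
            positions = _place_positions(gene, n_true + n_gdec, rng)
            roles = np.array([True] * n_true + [False] * n_gdec)
            rng.shuffle(roles)
            for pos, is_true in zip(positions, roles):
                _plant_site(seq, pos, is_true, config.pas_distance_range, rng)
                iv = GenomicInterval(chrom, pos, pos + 1, strand="+")
                (polya_sites if is_true else decoy_sites).append(iv)

        # Intergenic decoys: left flank gets the first share.
        inter = []
        if gene is None:
            inter = [GenomicInterval(chrom, 0, length)]
        else:
            if gene.start > 0:
                inter.append(GenomicInterval(chrom, 0, gene.start))
            if gene.end < length:
                inter.append(GenomicInterval(chrom, gene.end, length))
        for region, k in zip(inter, _distribute(idecoy_per_chrom[ci], max(len(inter), 1))):
            for pos in _place_positions(region, k, rng):
                _plant_site(seq, pos, False, config.pas_distance_range, rng)
                decoy_sites.append(GenomicInterval(chrom, pos, pos + 1, strand="+"))

        sequences[chrom] = "".join(seq)

    return SyntheticGenomeBundle(
        genome=Genome(sequences),
        polya_sites=polya_sites,
        gene_regions=gene_regions,
        decoy_sites=decoy_sites,
        config=config,
    )


def write_bundle(bundle: SyntheticGenomeBundle, outdir: str | Path) -> None:
    """Write genome.fa + polya_sites.bed + genes.bed + decoys.bed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome, outdir / "genome.fa")
    write_bed(bundle.polya_sites, outdir / "polya_sites.bed")
    write_bed(bundle.gene_regions, outdir / "genes.bed")
    write_bed(bundle.decoy_sites, outdir / "decoys.bed")


# ---------------------------------------------------------------------------
# Toy model stand-ins
# ---------------------------------------------------------------------------

EMBEDDING_DIM = 64


def toy_embedder(seq: str) -> np.ndarray:
    """Deterministic 64-dim composition embedding of a nucleotide sequence.

    Features: 4 mononucleotide frequencies, 16 dinucleotide frequencies,
    4 per-base positional centers of mass, 4 quarter-wise A densities;
    zero-padded to 64. Any two sequences differing at a PAS occurrence
    differ in at least one of these blocks.
    """
    if not seq:
        raise ValueError("cannot embed an empty sequence")
    n = len(seq)
    vec = np.zeros(EMBEDDING_DIM)
    idx = np.array([_BASE_INDEX.get(b, -1) for b in seq])
    valid = idx >= 0
    for b in range(4):
        vec[b] = np.mean(idx == b)
    if n > 1:
        for i in range(n - 1):
            a, b = idx[i], idx[i + 1]
            if a >= 0 and b >= 0:
                vec[4 + 4 * a + b] += 1.0 / (n - 1)
    positions = np.arange(n) / max(n - 1, 1)
    for b in range(4):
        mask = idx == b
        vec[20 + b] = positions[mask].mean() if mask.any() else 0.0
    quarters = np.array_split(np.asarray(idx == _BASE_INDEX["A"], float), 4)
    for qi, q in enumerate(quarters):
        vec[24 + qi] = q.mean() if len(q) else 0.0
    _ = valid  # N bases simply contribute to no feature
    return vec


def toy_scorer(seq: str) -> float:
    """Probability-like score for a 101-nt cleavage-oriented window.

    Keys on exactly what a trained sequence model learns here: an intact
    canonical PAS in the 10-35 nt upstream band, plus a T/G-rich downstream
    element. Decoys (PAS but no DSE) score lower than functional windows;
    PAS-ablated windows drop below 0.5.
    """
    if len(seq) != WINDOW:
        raise ValueError(f"scorer expects a {WINDOW}-nt window")
    has_pas = any(
        seq[s : s + 6] in CANONICAL_MOTIFS
        for s in range(CLEAVAGE_INDEX - 35, CLEAVAGE_INDEX - 9)
    )
    lo, hi = _DSE_SPAN
    down = seq[CLEAVAGE_INDEX + lo : CLEAVAGE_INDEX + hi]
    tg = sum(b in "TG" for b in down) / len(down)
    z = 4.0 * has_pas + 4.0 * (tg - 0.5) - 2.4
    return 1.0 / (1.0 + math.exp(-z))


def toy_attention(seq: str, kmer: int = 6) -> np.ndarray:
    """Row-stochastic token x token attention with PAS tokens boosted.

    The sequence is tokenized into non-overlapping k-mers. Attention
    received by a token (its column weight) is 1 plus a strong boost if the
    token is a canonical PAS hexamer, plus a mild A-richness term; rows are
    normalized to sum to 1.
    """
    if kmer <= 0:
        raise ValueError("kmer must be positive")
    if len(seq) < kmer:
        raise ValueError("sequence shorter than one token")
    n_tokens = len(seq) // kmer
    tokens = [seq[i * kmer : (i + 1) * kmer] for i in range(n_tokens)]
    weights = np.array(
        [
            1.0
            + 4.0 * (t in CANONICAL_MOTIFS)
            + 0.5 * t.count("A") / kmer
            for t in tokens
        ]
    )
    row = weights / weights.sum()
    return np.tile(row, (n_tokens, 1))
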