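"""Rule-based genome-wide scan for candidate poly(A) cleavage sites.

Stage 1 is a biological filter applied to every 101-nt window on both
strands. A window centered on position 50 is a candidate iff

1. the base at index 50 (the putative cleavage base) is ``A``,
2. the base immediately 5' of it (index 49) is ``C`` or ``G`` — cleavage
   occurs preferentially after CA/GA dinucleotides,
3. one of 18 polyadenylation-signal (PAS) hexamer variants starts 10-35 nt
   upstream of the cleavage base (window start index in [15, 40]).

Stage 2 attaches a probability from any pluggable sequence scorer (a callable
101-nt string -> [0, 1]); candidates below a threshold are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from .genome_io import Genome, reverse_complement

#: The 18 PAS hexamer variants, strongest first. The first two (AATAAA,
#: ATTAAA) are the canonical signals governing the large majority of sites.
PAS_MOTIFS: tuple[str, ...] = (
    "AATAAA", "ATTAAA", "AGTAAA", "CATAAA", "TATAAA", "GATAAA",
    "ACTAAA", "AATACA", "AATATA", "AAGAAA", "AATAGA", "AATGAA",
    "TTTAAA", "AAAATA", "TATATA", "AGATAA", "ATTACA", "AGAATA",
)

CANONICAL_MOTIFS: tuple[str, str] = ("AATAAA", "ATTAAA")

_DEFAULT_MOTIF_SET = frozenset(PAS_MOTIFS)

WINDOW = 101
CLEAVAGE_INDEX = 50
#: PAS start-to-cleavage distance band, inclusive.
MIN_PAS_DISTANCE = 10
MAX_PAS_DISTANCE = 35

SequenceScorer = Callable[[str], float]


@dataclass(frozen=True)
class CandidateSite:
    """A genomic position passing the Stage-1 filter.

    ``pos`` is always the forward-strand coordinate of the cleavage base;
    for minus-strand candidates it is the base complementary to the cleavage
    adenine. ``motif_distance`` is the window-local start-to-cleavage
    distance in nt.
    """

    chrom: str
    pos: int
    strand: str
    motif: str
    motif_distance: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not MIN_PAS_DISTANCE <= self.motif_distance <= MAX_PAS_DISTANCE:
            raise ValueError(
                f"motif distance {self.motif_distance} outside "
                f"[{MIN_PAS_DISTANCE}, {MAX_PAS_DISTANCE}]"
            )


def matches_candidate(
    window: str, motifs: Sequence[str] = PAS_MOTIFS
) -> tuple[bool, Optional[str], Optional[int]]:
    """Apply the Stage-1 filter to one 101-nt window.

    Returns ``(True, motif, distance)`` for the qualifying PAS match closest
    to the cleavage base, else ``(False, None, None)``. Windows with ``N``
    anywhere in the tested span (indices 15..50) never qualify.
    """
    if len(window) != WINDOW:
        raise ValueError(f"window must be {WINDOW} nt, got {len(window)}")
    if window[CLEAVAGE_INDEX] != "A" or window[CLEAVAGE_INDEX - 1] not in "CG":
        return False, None, None
    if "N" in window[CLEAVAGE_INDEX - MAX_PAS_DISTANCE : CLEAVAGE_INDEX + 1]:
        return False, None, None
    motif_set = (
        _DEFAULT_MOTIF_SET if motifs is PAS_MOTIFS else frozenset(motifs)
    )
    # Largest start index = smallest distance to cleavage; a given start
    # position holds exactly one hexamer, so no further tie-break is needed.
    for s in range(CLEAVAGE_INDEX - MIN_PAS_DISTANCE,
                   CLEAVAGE_INDEX - MAX_PAS_DISTANCE - 1, -1):
        hexamer = window[s : s + 6]
        if hexamer in motif_set:
            return True, hexamer, CLEAVAGE_INDEX - s
    return False, None, None


def scan_genome(
    genome: Genome,
    motifs: Sequence[str] = PAS_MOTIFS,
    scorer: Optional[SequenceScorer] = None,
    threshold: float = 0.5,
) -> list[CandidateSite]:
    """Single-nucleotide sliding-window scan of every chromosome, both strands.

    Every position with a full 101-nt window is tested on the forward strand;
    the minus strand is tested by applying the same filter to the reverse
    complement of the window. When ``scorer`` is given, surviving candidates
    are scored and only ``score >= threshold`` is emitted. Output is sorted
    by (chrom, pos, strand).
    """
    out: list[CandidateSite] = []
    flank = CLEAVAGE_INDEX
    for chrom in sorted(genome.chroms):
        seq = genome[chrom]
        n = len(seq)
        for p in range(flank, n - flank):
            # Cheap strand prefilters (conditions 1-2) before slicing windows.
            if seq[p] == "A" and seq[p - 1] in "CG":
                window = seq[p - flank : p + flank + 1]
                ok, motif, dist = matches_candidate(window, motifs)
                if ok:
                    site = CandidateSite(chrom, p, "+", motif, dist)
                    out.append(_maybe_score(site, window, scorer))
            if seq[p] == "T" and seq[p + 1] in "CG":
                window = reverse_complement(seq[p - flank : p + flank + 1])
                ok, motif, dist = matches_candidate(window, motifs)
                if ok:
                    site = CandidateSite(chrom, p, "-", motif, dist)
                    out.append(_maybe_score(site, window, scorer))
    if scorer is not None:
        out = [c for c in out if c.score is not None and c.score >= threshold]
    out.sort(key=lambda c: (c.chrom, c.pos, c.strand))
    return out


def _maybe_score(
    site: CandidateSite, window: str, scorer: Optional[SequenceScorer]
) -> CandidateSite:
    if scorer is None:
        return site
    s = float(scorer(window))
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"scorer returned {s}, outside [0, 1]")
    return replace(site, score=s)


def score_candidates(
    candidates: Sequence[CandidateSite],
    windows: Sequence[str],
    scorer: SequenceScorer,
) -> list[CandidateSite]:
    """Attach Stage-2 scores to pre-extracted candidate windows.

    ``candidates`` and ``windows`` are aligned 1:1 (window i is the 101-nt
    cleavage-oriented sequence of candidate i). The input list is not
    mutated; order is preserved.
    """
    if len(candidates) != len(windows):
        raise ValueError("candidates and windows must align 1:1")
    scored = []
    for cand, window in zip(candidates, windows):
        s = float(scorer(window))
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"scorer returned {s}, outside [0, 1]")
        scored.append(replace(cand, score=s))
    return scored


def candidate_window(genome: Genome, site: CandidateSite) -> str:
    """Extract the cleavage-oriented 101-nt window of a candidate."""
    seq = genome[site.chrom]
    window = seq[site.pos - CLEAVAGE_INDEX : site.pos + CLEAVAGE_INDEX + 1]
    return window if site.strand == "+" else reverse_complement(window)


def write_candidates_bed(
    candidates: Iterable[CandidateSite], path: str | Path
) -> None:
    """Write candidates as BED6: name ``motif:distance``, score 0-1000 or '.'."""
    with open(path, "w") as fh:
        for c in candidates:
            score = "." if c.score is None else str(round(1000 * c.score))
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.pos + 1}\t"
                f"{c.motif}:{c.motif_distance}\t{score}\t{c.strand}\n"
            )
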