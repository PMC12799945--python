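import re

import numpy as np
import pytest

from polyascan import synthetic_data as sd
from polyascan.genome_io import Genome, reverse_complement
from polyascan.pas_scanner import (
    PAS_MOTIFS,
    CandidateSite,
    matches_candidate,
    scan_genome,
    score_candidates,
    write_candidates_bed,
)

# --- independent brute-force oracles -------------------------------------

_MOTIF_RE = re.compile("|".join(f"(?=({m}))" for m in PAS_MOTIFS))


def oracle_match(window):
    """Regex re-implementation of the Stage-1 filter over one window."""
    if window[50] != "A" or window[49] not in "CG" or "N" in window[15:51]:
        return (False, None, None)
    best = None
    for m in _MOTIF_RE.finditer(window):
        s = m.start()
        if 15 <= s <= 40:
            dist = 50 - s
            if best is None or dist < best[1]:
                best = (window[s : s + 6], dist)
    if best is None:
        return (False, None, None)
    return (True, best[0], best[1])


def oracle_scan(genome):
    """Motif-first enumeration over both strands; full tuple set."""
    out = set()
    for chrom, seq in genome.items():
        n = len(seq)
        for strand in "+-":
            s2 = seq if strand == "+" else reverse_complement(seq)
            for m in _MOTIF_RE.finditer(s2):
                for d in range(10, 36):
                    p = m.start() + d
                    if p < 50 or p >= n - 50:
                        continue
                    ok, motif, dist = oracle_match(s2[p - 50 : p + 51])
                    if ok:
                        fwd = p if strand == "+" else n - 1 - p
                        out.add((chrom, fwd, strand, motif, dist))
    return out


def make_window(motif="AATAAA", start=30, before="C"):
    chars = list("G" * 101)
    chars[start : start + 6] = motif
    chars[49] = before
    chars[50] = "A"
    return "".join(chars)


# --- matches_candidate ----------------------------------------------------


class TestMatchesCandidate:
    def test_constructed_positive(self):
        w = make_window("AATAAA", start=30)
        assert matches_candidate(w) == (True, "AATAAA", 20)

    def test_condition2_failure(self):
        w = make_window("AATAAA", start=30, before="T")
        assert matches_candidate(w) == (False, None, None)

    def test_condition1_failure(self):
        w = make_window()
        w = w[:50] + "G" + w[51:]
        assert matches_candidate(w) == (False, None, None)

    def test_motif_outside_band_fails(self):
        for start in (9, 41):  # distances 41 and 9
            assert matches_candidate(make_window(start=start))[0] is False

    def test_band_boundaries_inclusive(self):
        assert matches_candidate(make_window(start=15)) == (True, "AATAAA", 35)
        assert matches_candidate(make_window(start=40)) == (True, "AATAAA", 10)

    def test_closest_motif_wins(self):
        w = list(make_window("AATAAA", start=16))
        w[30:36] = "ATTAAA"
        assert matches_candidate("".join(w)) == (True, "ATTAAA", 20)

    def test_n_in_tested_span_rejected(self):
        w = make_window()
        w = w[:20] + "N" + w[21:]
        assert matches_candidate(w) == (False, None, None)

    def test_n_outside_tested_span_tolerated(self):
        w = make_window()
        w = "N" + w[1:]
        assert matches_candidate(w)[0] is True

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            matches_candidate("ACGT")

    def test_agrees_with_regex_oracle_on_random_windows(self):
        rng = np.random.default_rng(42)
        n_positive_checked = 0
        for _ in range(3000):
            chars = rng.choice(list("ACGT"), size=101, p=[0.4, 0.1, 0.1, 0.4])
            # Bias toward passing conditions 1-2 so positives are exercised.
            chars[49] = "C" if rng.random() < 0.5 else "G"
            chars[50] = "A"
            w = "".join(chars)
            got, expected = matches_candidate(w), oracle_match(w)
            assert got == expected
            n_positive_checked += got[0]
        assert n_positive_checked > 100


# --- scan_genome ----------------------------------------------------------


def as_tuples(candidates):
    return {(c.chrom, c.pos, c.strand, c.motif, c.motif_distance) for c in candidates}


class TestScanGenome:
    def test_matches_brute_force_oracle(self, bundle):
        assert as_tuples(scan_genome(bundle.genome)) == oracle_scan(bundle.genome)

    def test_recovers_all_planted_sites(self, bundle):
        hits = {(c.chrom, c.pos) for c in scan_genome(bundle.genome) if c.strand == "+"}
        for site in bundle.polya_sites:
            assert (site.chrom, site.start) in hits

    def test_strand_symmetry_under_reverse_complement(self):
        b = sd.generate_genome(
            sd.SyntheticGenomeConfig(n_chroms=1, chrom_length=20_000, n_true_sites=10, n_decoy_sites=10, seed=3)
        )
        fwd = scan_genome(b.genome)
        rc = Genome({c: reverse_complement(s) for c, s in b.genome.items()})
        mirrored = {
            (c.chrom, b.genome.length(c.chrom) - 1 - c.pos,
             "-" if c.strand == "+" else "+", c.motif, c.motif_distance)
            for c in scan_genome(rc)
        }
        assert as_tuples(fwd) == mirrored

    def test_all_c_genome_empty(self):
        assert scan_genome(Genome({"c": "C" * 500})) == []

    def test_output_sorted(self, bundle):
        c = scan_genome(bundle.genome)
        keys = [(x.chrom, x.pos, x.strand) for x in c]
        assert keys == sorted(keys)

    def test_threshold_monotonicity(self, bundle):
        counts = [
            len(scan_genome(bundle.genome, scorer=sd.toy_scorer, threshold=t))
            for t in (0.0, 0.5, 0.8, 0.95, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestScoreCandidates:
    def _cands(self, n=3):
        return [
            CandidateSite("c", 60 + i, "+", "AATAAA", 20) for i in range(n)
        ], [make_window()] * n

    def test_constant_scorer_one(self):
        cands, wins = self._cands()
        scored = score_candidates(cands, wins, lambda s: 1.0)
        assert all(c.score == 1.0 for c in scored)

    def test_constant_zero_scorer_filtered_in_scan(self):
        g = Genome({"c": make_window() + "G" * 100})
        assert scan_genome(g, scorer=lambda s: 0.0, threshold=0.5) == []

    def test_input_not_mutated_and_order_kept(self):
        cands, wins = self._cands()
        scored = score_candidates(cands, wins, lambda s: 0.25)
        assert all(c.score is None for c in cands)
        assert [c.pos for c in scored] == [c.pos for c in cands]

    def test_out_of_range_score_rejected(self):
        cands, wins = self._cands(1)
        with pytest.raises(ValueError):
            score_candidates(cands, wins, lambda s: 1.5)

    def test_true_sites_outrank_decoys_with_toy_scorer(self, bundle):
        from conftest import site_window

        def mean_score(sites):
            cands = [CandidateSite(s.chrom, s.start, "+", "AATAAA", 20) for s in sites]
            wins = [site_window(bundle.genome, s.chrom, s.start) for s in sites]
            return np.mean([c.score for c in score_candidates(cands, wins, sd.toy_scorer)])

        assert mean_score(bundle.polya_sites) > mean_score(bundle.decoy_sites)


def test_write_candidates_bed(tmp_path):
    cands = [
        CandidateSite("chr1", 100, "+", "AATAAA", 20, score=0.8),
        CandidateSite("chr1", 200, "-", "ATTAAA", 12),
    ]
    p = tmp_path / "c.bed"
    write_candidates_bed(cands, p)
    lines = p.read_text().splitlines()
    assert lines[0] == "chr1\t100\t101\tAATAAA:20\t800\t+"
    assert lines[1] == "chr1\t200\t201\tATTAAA:12\t.\t-"
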