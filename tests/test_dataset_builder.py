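import re

import numpy as np
import pytest

from polyascan import dataset_builder as db
from polyascan.genome_io import Genome, GenomicInterval

# Independent regex oracle for the hard-negative rule: reference A at the
# cleavage index plus a canonical hexamer starting at window index 15..40.
_NEG_RE = re.compile("|".join(f"(?=({m}))" for m in ("AATAAA", "ATTAAA")))


def oracle_negative_ok(window):
    if window[50] != "A":
        return False
    return any(15 <= m.start() <= 40 for m in _NEG_RE.finditer(window))


def oracle_negative_loci(genome, sites, regions):
    out = set()
    for region in regions:
        seq = genome[region.chrom]
        for p in range(region.start + 50, region.end - 50):
            if p < 50 or p + 51 > len(seq):
                continue
            if not oracle_negative_ok(seq[p - 50 : p + 51]):
                continue
            if any(
                s.chrom == region.chrom and p - 50 < s.end and s.start < p + 51
                for s in sites
            ):
                continue
            out.add((region.chrom, p))
    return out


def tiny_genome():
    """Chromosome with one annotated site and one engineered negative locus."""
    chars = list("G" * 400)

    def plant(pos, motif="AATAAA", d=20):
        chars[pos - d : pos - d + 6] = motif
        chars[pos - 1] = "C"
        chars[pos] = "A"

    plant(100)   # annotated poly(A) site
    plant(300)   # unannotated → negative locus candidate
    return Genome({"c": "".join(chars)})


class TestBuildPositives:
    def test_window_centered_and_a_forced(self):
        g = Genome({"c": "G" * 101})
        site = GenomicInterval("c", 50, 51, strand="+")
        (w,) = db.build_positives(g, [site])
        assert len(w.seq) == 101 and w.seq[50] == "A" and w.label == 1

    def test_reference_base_overwritten_to_a(self):
        g = tiny_genome()
        site = GenomicInterval("c", 150, 151, strand="+")  # reference G
        (w,) = db.build_positives(g, [site])
        assert g["c"][150] == "G" and w.seq[50] == "A"

    def test_boundary_site_skipped(self):
        g = Genome({"c": "A" * 200})
        windows = db.build_positives(
            g, [GenomicInterval("c", 10, 11), GenomicInterval("c", 100, 101)]
        )
        assert len(windows) == 1 and windows[0].origin.start == 100

    def test_minus_strand_site_reverse_complemented(self):
        chars = list("G" * 201)
        chars[100] = "T"          # complement of cleavage A
        chars[101] = "C"          # complement G -> C at window index 49 after rc
        g = Genome({"c": "".join(chars)})
        (w,) = db.build_positives(g, [GenomicInterval("c", 100, 101, strand="-")])
        assert w.seq[50] == "A" and w.seq[49] == "G"


class TestBuildNegatives:
    def test_engineered_single_locus_found(self):
        g = tiny_genome()
        sites = [GenomicInterval("c", 100, 101, strand="+")]
        regions = [GenomicInterval("c", 0, 400)]
        loci = db.enumerate_negative_loci(g, sites, regions)
        assert {(l.chrom, l.start) for l in loci} == {("c", 300)}
        (w,) = db.build_negatives(g, sites, regions, "genic", 1, seed=0)
        assert w.origin.start == 300 and w.label == 0

    def test_matches_brute_force_enumeration(self, bundle):
        regions = bundle.gene_regions[:1]
        got = {
            (l.chrom, l.start)
            for l in db.enumerate_negative_loci(
                bundle.genome, bundle.polya_sites, regions
            )
        }
        assert got == oracle_negative_loci(
            bundle.genome, bundle.polya_sites, regions
        )

    def test_overlap_with_annotated_site_excluded(self):
        g = tiny_genome()
        # Annotate the engineered locus itself: nothing qualifies nearby.
        sites = [GenomicInterval("c", 300, 301, strand="+")]
        loci = db.enumerate_negative_loci(
            g, sites, [GenomicInterval("c", 200, 400)]
        )
        assert all(abs(l.start - 300) > 50 for l in loci)

    def test_n_zero_returns_empty(self):
        g = tiny_genome()
        assert db.build_negatives(
            g, [], [GenomicInterval("c", 0, 400)], "genic", 0
        ) == []

    def test_shortfall_raises_with_count(self):
        g = tiny_genome()
        with pytest.raises(ValueError, match="short by"):
            db.build_negatives(
                g, [], [GenomicInterval("c", 0, 400)], "genic", 10_000
            )

    def test_every_negative_passes_regex_oracle(self, bundle):
        neg = db.build_negatives(
            bundle.genome, bundle.polya_sites, bundle.gene_regions,
            "genic", 40, seed=7,
        )
        assert len(neg) == 40
        for w in neg:
            assert w.label == 0 and oracle_negative_ok(w.seq)

    def test_intergenic_mode_sources_outside_genes(self, bundle):
        neg = db.build_negatives(
            bundle.genome, bundle.polya_sites, bundle.gene_regions,
            "intergenic", 20, seed=7,
        )
        for w in neg:
            assert not any(
                g.start <= w.origin.start < g.end
                for g in bundle.gene_regions
                if g.chrom == w.origin.chrom
            )

    def test_seeded_determinism(self, bundle):
        args = (bundle.genome, bundle.polya_sites, bundle.gene_regions, "genic", 25)
        assert db.build_negatives(*args, seed=3) == db.build_negatives(*args, seed=3)


def make_windows(n, label, dataset="gene_gene"):
    base = "G" * 35 + "AATAAA" + "G" * 9 + "A" + "G" * 50
    assert len(base) == 101
    return [
        db.SequenceWindow(base, label, GenomicInterval("c", 1000 + i, 1001 + i), dataset)
        for i in range(n)
    ]


class TestBalanceAndSplit:
    def test_60_20_20_arithmetic(self):
        folds = db.balance_and_split(make_windows(100, 1), make_windows(100, 0), seed=0)
        assert len(folds) == 5
        for f in folds:
            assert (len(f.train), len(f.val), len(f.test)) == (120, 40, 40)
            for part in (f.train, f.val, f.test):
                labels = [w.label for w in part]
                assert labels.count(1) == labels.count(0)

    def test_downsampling_to_minority(self):
        folds = db.balance_and_split(make_windows(100, 1), make_windows(80, 0), seed=0)
        total = len(folds[0].train) + len(folds[0].val) + len(folds[0].test)
        assert total == 160

    def test_test_sets_partition_data(self):
        pos, neg = make_windows(100, 1), make_windows(100, 0)
        folds = db.balance_and_split(pos, neg, seed=1)
        seen = []
        for f in folds:
            seen.extend(id(w) for w in f.test)
        assert len(seen) == 200 and len(set(seen)) == 200

    def test_splits_disjoint_within_fold(self):
        folds = db.balance_and_split(make_windows(50, 1), make_windows(50, 0), seed=2)
        for f in folds:
            ids = [id(w) for part in (f.train, f.val, f.test) for w in part]
            assert len(ids) == len(set(ids))

    def test_seeded_reproducibility(self):
        pos, neg = make_windows(40, 1), make_windows(40, 0)
        a = db.balance_and_split(pos, neg, seed=9)
        b = db.balance_and_split(pos, neg, seed=9)
        for fa, fb in zip(a, b):
            assert [w.origin for w in fa.train] == [w.origin for w in fb.train]

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            db.balance_and_split([], make_windows(5, 0))


def test_write_dataset_table(tmp_path, bundle):
    pos = db.build_positives(bundle.genome, bundle.polya_sites)
    neg = db.build_negatives(
        bundle.genome, bundle.polya_sites, bundle.gene_regions, "genic",
        len(pos), seed=1,
    )
    folds = db.balance_and_split(pos, neg, seed=1)
    table = db.write_dataset(folds, tmp_path / "d.tsv")
    assert set(table.columns) >= {"sequence", "label", "fold", "split"}
    assert (tmp_path / "d.tsv").exists()
    assert sorted(table["split"].unique()) == ["test", "train", "val"]
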