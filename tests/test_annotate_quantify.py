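"""Window assignment, chain liftover, fractional counting, count matrices."""

import numpy as np
import pandas as pd
import pytest

from exomir.annotate_quantify import (AssignmentWindows, CountMatrix,
                                      SmallRNAAnnotation, assign_alignment,
                                      count_sample, count_sample_bruteforce,
                                      count_spikeins, liftover_interval,
                                      merge_counts, parse_chain_file,
                                      read_bed, write_bed)
from exomir.mini_align import AlignmentRecord, align_reads, build_index
from exomir.preprocess import TrimParams, trim_reads

W = AssignmentWindows()


def rec(chrom, start, end, strand="+", n=1, read_id="r"):
    return AlignmentRecord(read_id, chrom, start, end, strand, 0, n)


def ann(species, start, end, strand="+", chrom="chr1", cls="miRNA"):
    return SmallRNAAnnotation(species, cls, chrom, start, end, strand)


class TestAssignAlignment:
    def test_exact_coincidence(self):
        assert assign_alignment(rec("chr1", 100, 122), ann("m", 100, 122), W)

    def test_boundary_offsets_inclusive(self):
        # 5' offset -3 and 3' offset +3 are both still inside the windows
        assert assign_alignment(rec("chr1", 97, 125), ann("m", 100, 122), W)

    def test_five_prime_offset_beyond_window(self):
        # 5' offset +3 exceeds the +2 bound
        assert not assign_alignment(rec("chr1", 103, 122),
                                    ann("m", 100, 122), W)

    def test_windows_are_strand_oriented(self):
        a = ann("m", 100, 122, strand="-")
        # on the minus strand the 5' end is the genomic end: end offset -3
        # in genomic space is a +3 5' offset, outside the start window
        assert not assign_alignment(rec("chr1", 100, 119, "-"), a, W)
        # genomic start shifted +2 = 3' offset -2, allowed
        assert assign_alignment(rec("chr1", 102, 122, "-"), a, W)

    def test_strand_mismatch_never_assigns(self):
        assert not assign_alignment(rec("chr1", 100, 122, "-"),
                                    ann("m", 100, 122, "+"), W)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            AssignmentWindows(start_lo=1)


class TestLiftover:
    def _chain(self, tmp_path, text):
        p = tmp_path / "c.chain"
        p.write_text(text)
        return p

    def test_identity_chain_maps_unchanged(self, tmp_path):
        p = self._chain(tmp_path,
                        "chain 1000 chr1 10000 + 0 10000 chr1 10000 + 0 10000 1\n"
                        "10000\n")
        res = liftover_interval(("chr1", 500, 530, "+"), str(p))
        assert res.accepted and res.interval == ("chr1", 500, 530, "+")

    def test_constant_offset_chain_shifts(self, tmp_path):
        p = self._chain(tmp_path,
                        "chain 1000 chr1 10000 + 0 9000 chr2 12000 + 100 9100 1\n"
                        "9000\n")
        res = liftover_interval(("chr1", 500, 530, "-"), str(p))
        assert res.accepted and res.interval == ("chr2", 600, 630, "-")

    def test_interval_straddling_gap_rejected(self, tmp_path):
        # blocks [0,100) and [110,400): a 26 nt interval [90,116) maps only
        # 10 + 6 = 16 of 26 bases, below the 0.95 ratio
        p = self._chain(tmp_path,
                        "chain 1000 chr1 10000 + 0 400 chr1 10000 + 0 390 1\n"
                        "100 10 0\n"
                        "290\n")
        res = liftover_interval(("chr1", 90, 116, "+"), str(p))
        assert not res.accepted
        assert res.mapped_fraction == pytest.approx(16 / 26)

    def test_reverse_strand_chain_flips(self, tmp_path):
        p = self._chain(tmp_path,
                        "chain 1000 chr1 1000 + 0 1000 chr9 1000 - 0 1000 1\n"
                        "1000\n")
        res = liftover_interval(("chr1", 100, 130, "+"), str(p))
        assert res.accepted
        assert res.interval == ("chr9", 870, 900, "-")

    def test_unmapped_chromosome_rejected(self, tmp_path):
        p = self._chain(tmp_path,
                        "chain 1 chr1 100 + 0 100 chr1 100 + 0 100 1\n100\n")
        res = liftover_interval(("chr7", 10, 30, "+"), str(p))
        assert not res.accepted and "no chain" in res.reason

    def test_malformed_chain_raises_with_line(self, tmp_path):
        p = self._chain(tmp_path, "chain 1 chr1 100 + 0 100\n")
        with pytest.raises(ValueError, match=":1"):
            parse_chain_file(str(p))


class TestCountSample:
    def test_unique_read_adds_one(self):
        anns = [ann("mirA", 100, 122)]
        col, stats = count_sample({"r1": [rec("chr1", 100, 122)]}, anns, W)
        assert col["mirA"] == 1.0 and stats["assigned_mass"] == 1.0

    def test_fractional_multi_map_distribution(self):
        # 4 placements: two land in (multi-locus) species A windows, one in
        # B, one nowhere -> A +0.5, B +0.25, 0.25 unassigned
        anns = [ann("A", 100, 122), ann("A", 500, 522),
                ann("B", 900, 922, cls="piRNA")]
        placements = [rec("chr1", 100, 122, n=4), rec("chr1", 500, 522, n=4),
                      rec("chr1", 900, 922, n=4), rec("chr1", 2000, 2022, n=4)]
        col, stats = count_sample({"r1": placements}, anns, W)
        assert col["A"] == pytest.approx(0.5)
        assert col["B"] == pytest.approx(0.25)
        assert stats["assigned_mass"] == pytest.approx(0.75)

    def test_ambiguous_placement_split_and_logged(self):
        # two annotations equally distant from the placement
        anns = [ann("A", 100, 122), ann("B", 102, 124)]
        col, stats = count_sample({"r1": [rec("chr1", 101, 123)]}, anns, W)
        assert col["A"] == col["B"] == pytest.approx(0.5)
        assert stats["ambiguous_placements"] == 1

    def test_nearest_annotation_wins(self):
        anns = [ann("A", 100, 122), ann("B", 103, 125)]
        col, _ = count_sample({"r1": [rec("chr1", 100, 122)]}, anns, W)
        assert col["A"] == 1.0 and col["B"] == 0.0

    def test_zero_jitter_column_equals_truth(self, clean_experiment):
        genome, anns, spikes, sim = clean_experiment
        idx = build_index(genome)
        sample = sim.sheet["sample"][1]
        kept, _ = trim_reads(sim.reads[sample], TrimParams(adapter_seq=None))
        by_read, _ = align_reads(kept, idx)
        col, _ = count_sample(by_read, anns, W)
        truth = sim.truth.counts[sample]
        assert (col - truth).abs().max() == 0.0

    def test_matches_exhaustive_double_loop(self, messy_experiment):
        genome, anns, spikes, sim = messy_experiment
        idx = build_index(genome)
        sample = sim.sheet["sample"][0]
        kept, _ = trim_reads(sim.reads[sample], TrimParams())
        by_read, _ = align_reads(kept, idx)
        sub = dict(list(by_read.items())[:2000])
        fast = count_sample(sub, anns, W)[0]
        slow = count_sample_bruteforce(sub, anns, W)
        assert np.allclose(fast.values, slow.values)

    def test_widening_windows_is_monotone(self, messy_experiment):
        genome, anns, spikes, sim = messy_experiment
        idx = build_index(genome)
        sample = sim.sheet["sample"][0]
        kept, _ = trim_reads(sim.reads[sample], TrimParams())
        by_read, _ = align_reads(kept, idx)
        narrow = count_sample(by_read, anns, AssignmentWindows())[0]
        wide = count_sample(by_read, anns,
                            AssignmentWindows(-5, 4, -4, 5))[0]
        assert (wide.sum() >= narrow.sum() - 1e-9)

    def test_per_read_mass_never_exceeds_one(self, messy_experiment):
        genome, anns, spikes, sim = messy_experiment
        idx = build_index(genome)
        sample = sim.sheet["sample"][1]
        kept, _ = trim_reads(sim.reads[sample], TrimParams())
        by_read, _ = align_reads(kept, idx)
        for read_id, recs in list(by_read.items())[:500]:
            col, _ = count_sample({read_id: recs}, anns, W)
            assert col.sum() <= 1.0 + 1e-9


class TestSpikeins:
    def test_exact_match_counting(self):
        spikes = {"s1": "ACGTACGTACGTACGTACGTA", "s2": "TTTTGGGGCCCCAAAATTTTG"}
        reads = [("a", "ACGTACGTACGTACGTACGTA", ""),
                 ("b", "ACGTACGTACGTACGTACGTT", ""),  # 1 mismatch: rejected
                 ("c", "TTTTGGGGCCCCAAAATTTTG", "")]
        counts = count_spikeins(reads, spikes)
        assert counts["s1"] == 1 and counts["s2"] == 1


class TestMergeAndMatrix:
    def _columns(self, samples, species):
        rng = np.random.default_rng(0)
        return {s: pd.Series(rng.integers(0, 50, len(species)).astype(float),
                             index=species) for s in samples}

    def test_sample_sheet_order_and_shape(self):
        sheet = pd.DataFrame({"sample": [f"s{i}" for i in range(12)]})
        cols = self._columns(sheet["sample"], ["a", "b", "c"])
        m = merge_counts(cols, sheet, pd.Series("miRNA", index=["a", "b", "c"]),
                         {s: 100 for s in sheet["sample"]},
                         {s: 10 for s in sheet["sample"]})
        assert list(m.counts.columns) == list(sheet["sample"])
        assert m.counts.shape == (3, 12)

    def test_missing_species_zero_filled(self):
        sheet = pd.DataFrame({"sample": ["s1", "s2"]})
        cols = {"s1": pd.Series({"a": 5.0}), "s2": pd.Series({"b": 3.0})}
        m = merge_counts(cols, sheet, pd.Series({"a": "miRNA", "b": "piRNA"}),
                         {"s1": 10, "s2": 10}, {"s1": 1, "s2": 1})
        assert m.counts.loc["a", "s2"] == 0.0
        assert m.counts.loc["b", "s1"] == 0.0

    def test_permuted_columns_give_identical_matrix(self):
        sheet = pd.DataFrame({"sample": ["s1", "s2", "s3"]})
        cols = self._columns(["s1", "s2", "s3"], ["a", "b"])
        perm = {k: cols[k] for k in ["s3", "s1", "s2"]}
        cls = pd.Series("miRNA", index=["a", "b"])
        tot = {s: 1 for s in cols}
        m1 = merge_counts(cols, sheet, cls, tot, tot)
        m2 = merge_counts(perm, sheet, cls, tot, tot)
        assert m1.counts.equals(m2.counts)

    def test_duplicate_sample_ids_rejected(self):
        sheet = pd.DataFrame({"sample": ["s1", "s1"]})
        with pytest.raises(ValueError, match="duplicate"):
            merge_counts(self._columns(["s1"], ["a"]), sheet,
                         pd.Series({"a": "miRNA"}), {"s1": 1}, {"s1": 1})

    def test_tsv_round_trip(self, tmp_path):
        sheet = pd.DataFrame({"sample": ["s1", "s2"]})
        cols = self._columns(["s1", "s2"], ["a", "b"])
        m = merge_counts(cols, sheet, pd.Series({"a": "miRNA", "b": "piRNA"}),
                         {"s1": 7, "s2": 9}, {"s1": 2, "s2": 3})
        m.to_tsv(tmp_path / "c.tsv", tmp_path / "c.json")
        back = CountMatrix.from_tsv(tmp_path / "c.tsv", tmp_path / "c.json")
        assert np.allclose(back.counts.values, m.counts.values)
        assert back.total_mapped.equals(m.total_mapped)


def test_bed_round_trip(tmp_path):
    anns = [ann("mirA", 10, 32), ann("pirB", 50, 80, "-", cls="piRNA")]
    write_bed(anns, tmp_path / "a.bed")
    assert read_bed(tmp_path / "a.bed") == anns
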