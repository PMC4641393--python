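import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmcensus.census import (
    GenomeCensusRow,
    aggregate_histogram,
    genome_census,
    select_cellular_representatives,
    select_representatives,
    shared_gene_fraction,
    stratify_by_length,
)
from tmcensus.io_formats import GenomeMetadata, OrthogroupTable, ProteinRecord
from tmcensus.tm_predictor import TMSegment, TopologyPrediction


def _protein(pid, length=100, genome="g1"):
    return ProteinRecord(pid, genome, "A" * length)


def _pred(pid, k):
    segs = tuple(TMSegment(1 + 40 * i, 20 + 40 * i) for i in range(k))
    return TopologyPrediction(pid, segs, "in")


class TestGenomeCensus:
    def test_counts_and_fraction(self):
        proteins = [_protein(f"p{i}") for i in range(10)]
        preds = {f"p{i}": _pred(f"p{i}", 1 if i < 2 else 0) for i in range(10)}
        row = genome_census(proteins, preds)
        assert row.n_tm == 2
        assert row.tm_fraction == pytest.approx(0.2)

    def test_all_soluble_genome_has_zero_fraction(self):
        # mirrors the lone real-world case of a phage with no TM protein at all
        proteins = [_protein(f"p{i}") for i in range(11)]
        preds = {f"p{i}": _pred(f"p{i}", 0) for i in range(11)}
        assert genome_census(proteins, preds).tm_fraction == 0.0

    def test_capped_histogram_hand_binned(self):
        counts = [0, 1, 1, 2, 6]
        proteins = [_protein(f"p{i}") for i in range(5)]
        preds = {f"p{i}": _pred(f"p{i}", k) for i, k in enumerate(counts)}
        row = genome_census(proteins, preds)
        assert row.capped_histogram(cap=4) == {"0": 1, "1": 2, "2": 1, "4+": 1}

    def test_missing_prediction_lists_ids(self):
        proteins = [_protein("p0"), _protein("p1")]
        with pytest.raises(ValueError, match="p1"):
            genome_census(proteins, {"p0": _pred("p0", 0)})

    def test_cross_tab_margins(self):
        proteins = [_protein(f"p{i}") for i in range(6)]
        preds = {f"p{i}": _pred(f"p{i}", i % 2) for i in range(6)}
        groups = OrthogroupTable({"p0": "g", "p1": "g", "p2": "h"})
        row = genome_census(proteins, preds, groups)
        (a, b), (c, d) = row.cross_tab
        assert a + b == row.n_tm
        assert a + c == row.n_in_orthogroups == 3
        assert a + b + c + d == row.n_proteins

    def test_invariant_violation_rejected(self):
        with pytest.raises(ValueError):
            GenomeCensusRow("g", 3, 2, {0: 2, 1: 1}, 0, ((1, 1), (0, 1)))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.integers(0, 8), min_size=1, max_size=40),
           st.lists(st.integers(0, 8), min_size=1, max_size=40))
    def test_census_additivity_on_fuzzed_genomes(self, counts_a, counts_b):
        """The census of a union of two disjoint genome sets is the
        element-wise sum of the two censuses."""
        def rows_for(counts, genome):
            proteins = [_protein(f"{genome}p{i}", genome=genome)
                        for i in range(len(counts))]
            preds = {p.protein_id: _pred(p.protein_id, k)
                     for p, k in zip(proteins, counts)}
            return genome_census(proteins, preds)

        ra = rows_for(counts_a, "ga")
        rb = rows_for(counts_b, "gb")
        pooled = aggregate_histogram([ra, rb])
        for k in set(ra.histogram) | set(rb.histogram):
            assert pooled[k] == ra.histogram.get(k, 0) + rb.histogram.get(k, 0)
        assert sum(ra.histogram.values()) == ra.n_proteins
        assert sum(rb.histogram.values()) == rb.n_proteins
        assert ra.n_tm + rb.n_tm == sum(v for k, v in pooled.items() if k >= 1)


class TestAggregateHistogram:
    def test_pooling(self):
        r1 = GenomeCensusRow("g1", 10, 5, {0: 5, 1: 5}, 0, ((0, 5), (0, 5)))
        r2 = GenomeCensusRow("g2", 10, 5, {0: 5, 2: 5}, 0, ((0, 5), (0, 5)))
        assert aggregate_histogram([r1, r2]) == {0: 10, 1: 5, 2: 5}

    def test_normalized(self):
        r1 = GenomeCensusRow("g1", 10, 5, {0: 5, 1: 5}, 0, ((0, 5), (0, 5)))
        r2 = GenomeCensusRow("g2", 10, 5, {0: 5, 2: 5}, 0, ((0, 5), (0, 5)))
        assert aggregate_histogram([r1, r2], normalize=True) == \
            {0: 0.5, 1: 0.25, 2: 0.25}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_histogram([])


class TestStratifyByLength:
    def test_bin_assignment(self):
        proteins = [_protein("p0", length=150)]
        strat = stratify_by_length(proteins, {"p0": _pred("p0", 0)}, bin_width=100)
        assert list(strat.counts) == [100]

    def test_classes_pooled_at_4(self):
        proteins = [_protein("p0", length=50), _protein("p1", length=250)]
        preds = {"p0": _pred("p0", 1), "p1": _pred("p1", 6)}
        strat = stratify_by_length(proteins, preds, bin_width=100)
        assert strat.counts[0] == {"1": 1}
        assert strat.counts[200] == {"4+": 1}

    def test_proportions_sum_to_one(self, default_dataset):
        truth_preds = default_dataset.truth.as_predictions()
        proteins = [p for v in default_dataset.proteomes.values() for p in v]
        strat = stratify_by_length(proteins, truth_preds, bin_width=100)
        for lo, props in strat.proportions().items():
            assert sum(props.values()) == pytest.approx(1.0)

    def test_narrow_bins_rejected(self):
        with pytest.raises(ValueError):
            stratify_by_length([], {}, bin_width=5)


class TestSelectRepresentatives:
    def test_redundant_pair_collapses(self):
        groups = {"A": set(range(20)), "B": set(range(19)) | {99}}
        assert shared_gene_fraction(groups["A"], groups["B"]) == pytest.approx(0.95)
        kept = select_representatives(groups, threshold=0.9, seed=0)
        assert len(kept) == 1

    def test_distinct_pair_kept(self):
        groups = {"A": set(range(10)), "B": set(range(5, 15))}
        assert len(select_representatives(groups, threshold=0.9, seed=0)) == 2

    def test_transitive_closure_single_linkage(self):
        # A-B at 0.92, B-C at 0.91, A-C at 0.80 -> one component
        a = set(range(100))
        b = set(range(8, 103))          # |a&b|/100 = 0.92
        c = set(range(17, 108)) | {200, 201, 202, 203, 204, 205, 206, 207, 208}
        ab = shared_gene_fraction(a, b)
        bc = shared_gene_fraction(b, c)
        ac = shared_gene_fraction(a, c)
        assert ab >= 0.9 and bc >= 0.9 and ac < 0.9
        kept = select_representatives({"A": a, "B": b, "C": c}, threshold=0.9, seed=3)
        assert len(kept) == 1

    def test_threshold_one_with_distinct_sets_is_identity(self):
        groups = {f"G{i}": {f"x{i}a", f"x{i}b", "shared"} for i in range(5)}
        kept = select_representatives(groups, threshold=1.0, seed=0)
        assert kept == set(groups)

    def test_retained_count_equals_components_for_any_seed(self):
        groups = {"A": set(range(20)), "B": set(range(20)),
                  "C": {100, 101, 102}, "D": {200, 201}}
        for seed in range(10):
            kept = select_representatives(groups, threshold=0.9, seed=seed)
            assert len(kept) == 3
            assert len(kept & {"A", "B"}) == 1

    def test_zero_group_genome_kept(self, caplog):
        groups = {"A": set(range(10)), "Z": set()}
        kept = select_representatives(groups, threshold=0.9, seed=0)
        assert "Z" in kept

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            select_representatives({}, threshold=0.0)


class TestSelectCellularRepresentatives:
    @staticmethod
    def _md(gid, genus):
        return GenomeMetadata(gid, gid, "bacterium", None, None, "unknown", genus)

    def test_largest_genome_per_genus(self):
        md = {"g1": self._md("g1", "Escherichia"), "g2": self._md("g2", "Escherichia")}
        kept = select_cellular_representatives(md, {"g1": 3000, "g2": 2500})
        assert kept == {"g1"}

    def test_single_member_genus(self):
        md = {"g1": self._md("g1", "Bacillus")}
        assert select_cellular_representatives(md, {"g1": 10}) == {"g1"}

    def test_tie_goes_to_smaller_id(self):
        md = {"gB": self._md("gB", "X"), "gA": self._md("gA", "X")}
        assert select_cellular_representatives(md, {"gA": 2000, "gB": 2000}) == {"gA"}

    def test_missing_genus_kept(self):
        md = {"g1": GenomeMetadata("g1", "g1", "bacterium")}
        assert select_cellular_representatives(md, {"g1": 10}) == {"g1"}

    def test_viruses_ignored(self):
        md = {"v1": GenomeMetadata("v1", "v1", "virus", "Myoviridae", "Bacteria")}
        assert select_cellular_representatives(md, {"v1": 10}) == set()


class TestCensusOnGroundTruth:
    def test_truth_predictions_reproduce_planted_fractions_exactly(self, default_dataset):
        truth_preds = default_dataset.truth.as_predictions()
        for genome_id, proteins in default_dataset.proteomes.items():
            row = genome_census(proteins, truth_preds, default_dataset.orthogroups)
            assert row.tm_fraction == pytest.approx(
                default_dataset.truth.genome_tm_fraction[genome_id], abs=1e-12)

    def test_repredicted_fraction_close_to_planted(self, default_dataset,
                                                   default_predictions):
        for genome_id, proteins in default_dataset.proteomes.items():
            row = genome_census(proteins, default_predictions)
            planted = default_dataset.truth.genome_tm_fraction[genome_id]
            assert abs(row.tm_fraction - planted) <= 0.05
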