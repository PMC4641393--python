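"""Statistical operations, checked against exhaustive-enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmcensus.census import GenomeCensusRow
from tmcensus.group_compare import (
    build_labeling,
    chisq_test,
    correlate,
    mww_test,
    orthogroup_consistency,
)
from tmcensus.io_formats import GenomeMetadata, OrthogroupTable
from tmcensus.tm_predictor import TMSegment, TopologyPrediction


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_mww(a, b):
    """Exhaustive two-sided MWW: U by pair counting, p over all labelings."""
    def u_of(x, y):
        u = 0.0
        for xi in x:
            for yj in y:
                u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
        return u

    n, m = len(a), len(b)
    pooled = list(a) + list(b)
    center = n * m / 2
    dev = abs(u_of(a, b) - center)
    hits = total = 0
    for idx in itertools.combinations(range(n + m), n):
        x = [pooled[i] for i in idx]
        y = [pooled[i] for i in range(n + m) if i not in idx]
        total += 1
        if abs(u_of(x, y) - center) >= dev - 1e-9:
            hits += 1
    return u_of(a, b), hits / total


def oracle_chisq(table):
    """Pearson statistic by the textbook formula."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - e) ** 2 / e
    return stat


class TestMWW:
    def test_identical_samples_give_p_one(self):
        res = mww_test([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        res = mww_test([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 labelings as extreme

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(1, 4), st.integers(1, 4), st.data())
    def test_matches_enumeration_oracle_small_samples(self, n, m, data):
        """All n+m <= 8, drawn from a small alphabet so ties are common."""
        a = data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n))
        b = data.draw(st.lists(st.integers(0, 5), min_size=m, max_size=m))
        u_exp, p_exp = oracle_mww(a, b)
        res = mww_test(a, b)
        assert res.u == pytest.approx(u_exp)
        assert res.p_value == pytest.approx(p_exp)

    def test_consistency_under_shift(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, 60)
        b = rng.normal(1.5, 1.0, 60)
        assert mww_test(a, b).p_value < 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mww_test([], [1.0])

    def test_p_display_floor(self):
        from tmcensus.group_compare import MWWResult
        assert MWWResult(0, 1e-20, "asymptotic").p_display() == "< 2e-16"
        assert MWWResult(0, 0.25, "exact").p_display() == "0.25"


class TestChiSquared:
    def test_identical_histograms(self):
        res = chisq_test(hist_a={0: 10, 1: 10}, hist_b={0: 10, 1: 10})
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_2x2_hand_computed(self):
        res = chisq_test([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.dof == 1

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 10), st.integers(0, 10)),
                    min_size=2, max_size=5))
    def test_matches_pearson_formula_small_tables(self, cols):
        table = np.array(cols).T
        # keep tables valid and above the merge threshold so no merging occurs
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return
        exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if exp.min() < 5:
            return
        res = chisq_test(table)
        assert res.statistic == pytest.approx(oracle_chisq(table))

    def test_sparse_tail_bins_merged_rightward(self):
        res = chisq_test(hist_a={0: 50, 1: 40, 5: 1}, hist_b={0: 45, 1: 44, 5: 2})
        assert res.n_bins == 2  # the k=5 tail folds into its neighbour

    def test_null_compositions_rarely_reject(self):
        """Two samples from one residue distribution: non-significant at
        alpha = 0.05 in >= 90 % of seeded replicates."""
        rejections = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            c1 = np.bincount(rng.integers(0, 20, 2000), minlength=20)
            c2 = np.bincount(rng.integers(0, 20, 2000), minlength=20)
            if chisq_test(np.vstack([c1, c2])).p_value < 0.05:
                rejections += 1
        assert rejections <= 10

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            chisq_test([[5], [5]])


class TestCorrelate:
    @staticmethod
    def _row(gid, n, n_tm):
        hist = {0: n - n_tm, 1: n_tm}
        return GenomeCensusRow(gid, n, n_tm, hist, 0, ((0, n_tm), (0, n - n_tm)))

    @staticmethod
    def _label(gid, lipid):
        return {gid: {"lipid_binary": lipid, "host_domain_binary": 0,
                      "family": None, "host_domain": "Bacteria"}}

    def test_zero_variance_rejected(self):
        rows = [self._row(f"g{i}", 10, 2) for i in range(4)]
        labels = {}
        for i in range(4):
            labels.update(self._label(f"g{i}", i % 2))
        with pytest.raises(ValueError):
            correlate(rows, labels, "lipid_binary")

    def test_point_biserial_closed_form_on_separated_toy(self):
        # lipid genomes at fraction 0.3, non-lipid at 0.05: compare with the
        # closed-form point-biserial r = (m1-m0)/s * sqrt(p*q)
        rows = [self._row(f"l{i}", 100, 30) for i in range(3)] + \
               [self._row(f"n{i}", 100, 5) for i in range(3)]
        labels = {}
        for i in range(3):
            labels.update(self._label(f"l{i}", 1))
            labels.update(self._label(f"n{i}", 0))
        y = np.array([0.3] * 3 + [0.05] * 3)
        x = np.array([1, 1, 1, 0, 0, 0])
        expected = ((y[x == 1].mean() - y[x == 0].mean())
                    / y.std() * math.sqrt(0.5 * 0.5))
        r = correlate(rows, labels, "lipid_binary")
        assert r == pytest.approx(expected)
        assert r == pytest.approx(1.0)  # perfectly separated, zero within-group spread

    def test_affine_invariance_of_sign_and_magnitude(self):
        rng = np.random.default_rng(2)
        rows = [self._row(f"g{i}", 100, int(rng.integers(1, 40)))
                for i in range(8)]
        labels = {}
        for i in range(8):
            labels.update(self._label(f"g{i}", i % 2))
        r1 = correlate(rows, labels, "lipid_binary")
        # rescale the covariate affinely: 0/1 -> 10/30
        for i in range(8):
            labels[f"g{i}"]["lipid_binary"] = 10 + 20 * (i % 2)
        r2 = correlate(rows, labels, "lipid_binary")
        assert r1 == pytest.approx(r2)

    def test_needs_three_genomes(self):
        with pytest.raises(ValueError):
            correlate([self._row("a", 10, 1)], {}, "n_proteins")

    def test_planted_lipid_effect_recovered(self, default_dataset,
                                            default_predictions):
        from tmcensus.census import census_all

        rows = census_all(default_dataset.proteomes, default_predictions)
        virus_rows = [r for r in rows
                      if default_dataset.metadata[r.genome_id].is_virus]
        labeling = build_labeling(default_dataset.metadata)
        r = correlate(virus_rows, labeling, "lipid_binary")
        assert r > 0.5  # strong positive, by construction of the generator


class TestOrthogroupConsistency:
    @staticmethod
    def _preds(counts_by_pid):
        return {
            pid: TopologyPrediction(
                pid, tuple(TMSegment(1 + 40 * i, 20 + 40 * i) for i in range(k)),
                "in")
            for pid, k in counts_by_pid.items()
        }

    def test_uniform_group(self):
        preds = self._preds({"a": 2, "b": 2, "c": 2})
        rep = orthogroup_consistency(preds, OrthogroupTable(
            {"a": "g", "b": "g", "c": "g"}))
        assert rep.fraction_uniform == 1.0

    def test_hand_counted_mixture(self):
        preds = self._preds({"a1": 1, "a2": 1, "b1": 1, "b2": 2, "c1": 3, "c2": 5})
        table = OrthogroupTable({"a1": "A", "a2": "A", "b1": "B", "b2": "B",
                                 "c1": "C", "c2": "C"})
        rep = orthogroup_consistency(preds, table)
        assert rep.fraction_uniform == pytest.approx(1 / 3)
        assert rep.discordant_by_one == pytest.approx(1 / 2)
        assert rep.discordant_by_two == pytest.approx(1 / 2)

    def test_singleton_groups_ignored(self):
        preds = self._preds({"a": 1, "b": 2, "c": 2})
        table = OrthogroupTable({"a": "A", "b": "B", "c": "B"})
        rep = orthogroup_consistency(preds, table)
        assert rep.n_groups == 1

    def test_no_multi_member_group_rejected(self):
        preds = self._preds({"a": 1})
        with pytest.raises(ValueError):
            orthogroup_consistency(preds, OrthogroupTable({"a": "A"}))

    def test_permutation_invariance(self):
        counts = {"a": 1, "b": 3, "c": 2, "d": 2}
        table = OrthogroupTable({k: "G" for k in counts})
        rep1 = orthogroup_consistency(self._preds(counts), table)
        shuffled = dict(reversed(list(counts.items())))
        rep2 = orthogroup_consistency(self._preds(shuffled), table)
        assert rep1.fraction_uniform == rep2.fraction_uniform
        assert rep1.groups[0].tm_counts == rep2.groups[0].tm_counts

    def test_synthetic_orthogroups_mostly_uniform(self, default_dataset,
                                                  default_predictions):
        rep = orthogroup_consistency(default_predictions,
                                     default_dataset.orthogroups)
        assert rep.fraction_uniform >= 0.9


class TestNullCalibration:
    def test_mww_null_rejection_rate(self):
        """Under the null, the exact test at alpha = 0.05 rejects in
        5 % +/- 2 % of replicates (discreteness keeps it slightly below)."""
        rng = np.random.default_rng(123)
        rejections = sum(
            mww_test(rng.normal(size=10), rng.normal(size=10)).p_value < 0.05
            for _ in range(1000)
        )
        assert 30 <= rejections <= 70
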