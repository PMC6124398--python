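import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from drugrepo import (ContingencyTable, EnrichmentScreen, bh_adjust,
                      build_contingency, build_universe, fisher_exact_upper,
                      generate, rank_for_disease, screen_all_pairs)
from drugrepo.enrichment import DegenerateTableError
from drugrepo.networks import (DGINetwork, DiseaseRecord, DrugRecord,
                               GDANetwork, GeneRef)
from drugrepo.simulate import SyntheticConfig


def hypergeom_upper_tail_exact(a, b, c, d):
    """Independent oracle: exact rational upper-tail hypergeometric sum."""
    n, K, M = a + b + c + d, a + b, a + c
    total = sum(math.comb(K, k) * math.comb(n - K, M - k)
                for k in range(a, min(K, M) + 1))
    return Fraction(total, math.comb(n, M))


def _nets(drug_targets, disease_genes):
    dgi = DGINetwork()
    for drug_id, ids in drug_targets.items():
        dgi.drugs[drug_id] = DrugRecord(drug_id=drug_id,
                                        targets={GeneRef(i) for i in ids})
    gda = GDANetwork()
    for mesh_id, ids in disease_genes.items():
        gda.diseases[mesh_id] = DiseaseRecord(mesh_id=mesh_id,
                                              genes={GeneRef(i) for i in ids})
    return dgi, gda


class TestBuildUniverse:
    def test_modes(self):
        dgi, gda = _nets({"D": {1, 2, 3}}, {"M": {2, 3, 4}})
        ids = lambda s: {g.entrez_id for g in s}
        assert ids(build_universe(dgi, gda, "intersection")) == {2, 3}
        assert ids(build_universe(dgi, gda, "gda_all")) == {2, 3, 4}
        assert ids(build_universe(dgi, gda, "union")) == {1, 2, 3, 4}

    def test_modes_agree_on_identical_pools(self):
        dgi, gda = _nets({"D": {1, 2}}, {"M": {1, 2}})
        sets = [build_universe(dgi, gda, m)
                for m in ("intersection", "gda_all", "union")]
        assert sets[0] == sets[1] == sets[2]

    def test_empty_universe_errors(self):
        dgi, gda = _nets({"D": {1}}, {"M": {2}})
        with pytest.raises(ValueError, match="empty"):
            build_universe(dgi, gda, "intersection")

    def test_unknown_mode(self):
        dgi, gda = _nets({"D": {1}}, {"M": {1}})
        with pytest.raises(ValueError):
            build_universe(dgi, gda, "everything")


class TestBuildContingency:
    def test_worked_examples(self):
        uni = {GeneRef(i) for i in range(1, 11)}
        dgi, gda = _nets({"D": {1, 2}}, {"M": {2, 3}})
        t = build_contingency(dgi.drugs["D"], gda.diseases["M"], uni)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 7)

        uni20 = {GeneRef(i) for i in range(1, 21)}
        dgi, gda = _nets({"D": {1, 2, 3}}, {"M": {4, 5, 6, 7}})
        t = build_contingency(dgi.drugs["D"], gda.diseases["M"], uni20)
        assert (t.a, t.b, t.c, t.d) == (0, 3, 4, 13)

    def test_random_sets_match_bruteforce(self, rng):
        uni_ids = list(range(1, 51))
        uni = {GeneRef(i) for i in uni_ids}
        for _ in range(50):
            tids = set(rng.choice(uni_ids, rng.integers(1, 20), replace=False).tolist())
            dids = set(rng.choice(uni_ids, rng.integers(1, 30), replace=False).tolist())
            dgi, gda = _nets({"D": tids}, {"M": dids})
            t = build_contingency(dgi.drugs["D"], gda.diseases["M"], uni)
            assert t.a == len(tids & dids)
            assert t.b == len(tids - dids)
            assert t.c == len(dids - tids)
            assert t.d == 50 - len(tids | dids)
            assert t.n == 50

    def test_degenerate_pair_signals(self):
        uni = {GeneRef(1), GeneRef(2)}
        dgi, gda = _nets({"D": {99}}, {"M": {1}})
        with pytest.raises(DegenerateTableError):
            build_contingency(dgi.drugs["D"], gda.diseases["M"], uni)


class TestFisherExactUpper:
    def test_minimal_overlap_is_exactly_one(self):
        # a=0 is the tail over the whole support when 0 is feasible
        assert fisher_exact_upper(ContingencyTable(0, 3, 4, 13)) == 1.0

    @pytest.mark.parametrize("table", [(1, 1, 1, 7), (5, 5, 5, 85),
                                       (3, 0, 2, 5), (2, 8, 10, 80)])
    def test_matches_exact_enumeration(self, table):
        p = fisher_exact_upper(ContingencyTable(*table))
        assert abs(p - float(hypergeom_upper_tail_exact(*table))) < 1e-12

    def test_monotone_decreasing_in_overlap(self):
        # margins fixed at K=10, M=15, n=60
        K, M, n = 10, 15, 60
        ps = []
        for a in range(0, min(K, M) + 1):
            ps.append(fisher_exact_upper(
                ContingencyTable(a, K - a, M - a, n - K - M + a)))
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)

    def test_two_sided_flag(self):
        t = ContingencyTable(4, 1, 2, 13)
        from scipy.stats import fisher_exact

        expected = fisher_exact([[4, 1], [2, 13]], alternative="two-sided")[1]
        assert fisher_exact_upper(t, alternative="two-sided") == pytest.approx(expected)


class TestBHAdjust:
    def test_identical_pvalues_unchanged(self):
        q = bh_adjust([0.03] * 5)
        assert np.allclose(q, 0.03)

    def test_stepup_hand_computation(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_test_identity(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_q_dominates_p_and_preserves_order(self, pvals):
        p = np.asarray(pvals)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_family_larger_than_vector(self):
        # m larger than the vector scales every q up
        q1 = bh_adjust([0.01, 0.02])
        q2 = bh_adjust([0.01, 0.02], m=4)
        assert np.allclose(q2, 2 * q1)
        with pytest.raises(ValueError):
            bh_adjust([0.01, 0.02], m=1)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestScreenAllPairs:
    def test_disjoint_genes_nothing_tested(self):
        dgi, gda = _nets({"D": {1, 2}}, {"M": {1, 2, 3}, "M2": {1, 3}})
        # remove overlap for one pair only: drug shares no gene with M2?
        dgi2, gda2 = _nets({"D": {9}}, {"M": {1, 2}})
        with pytest.warns(UserWarning, match="no testable"):
            # universe union so both sides survive, but no overlap
            report = screen_all_pairs(dgi2, gda2, universe_mode="union")
        assert report.n_pairs_tested == 0

    def test_equal_tables_share_p_and_q(self):
        dgi, gda = _nets({"D1": {1, 2}, "D2": {1, 2}},
                         {"M": {1, 5, 6}})
        report = screen_all_pairs(dgi, gda, universe_mode="union")
        assert report.n_pairs_tested == 2
        p1, p2 = (r.p_value for r in report.results)
        q1, q2 = (r.q_value for r in report.results)
        assert p1 == p2 and q1 == q2 == p1  # step-up on equal p gives q == p

    def test_planted_pairs_dominate_same_disease(self, small_planted):
        _, dgi, gda, truth = small_planted
        report = screen_all_pairs(dgi, gda)
        by_disease = {}
        for r in report.results:
            by_disease.setdefault(r.mesh_id, []).append(r)
        for drug_id, mesh_id in truth.planted_pairs:
            peers = by_disease[mesh_id]
            planted_p = next(r.p_value for r in peers if r.drug_id == drug_id)
            others = [r.p_value for r in peers
                      if (r.drug_id, r.mesh_id) not in truth.planted_pairs]
            assert all(planted_p < p for p in others)

    def test_overlap_genes_match_table(self, small_planted):
        _, dgi, gda, _ = small_planted
        report = screen_all_pairs(dgi, gda)
        for r in report.results:
            assert len(r.overlap_genes) == r.table.a
            assert r.table.n == report.universe_size

    def test_screen_is_deterministic(self, small_planted):
        _, dgi, gda, _ = small_planted
        r1 = screen_all_pairs(dgi, gda)
        r2 = screen_all_pairs(dgi, gda)
        assert [(x.drug_id, x.mesh_id, x.p_value, x.q_value)
                for x in r1.results] == [
            (x.drug_id, x.mesh_id, x.p_value, x.q_value) for x in r2.results]


class TestRankForDisease:
    def _report(self):
        cfg = SyntheticConfig(n_genes=400, n_drugs=30, n_diseases=5,
                              targets_per_drug=5, genes_per_disease=40,
                              n_planted=3, planted_overlap_fraction=1.0,
                              seed=11)
        dgi, gda, truth = generate(cfg)
        return screen_all_pairs(dgi, gda), truth

    def test_threshold_and_ranks(self, small_planted):
        _, dgi, gda, truth = small_planted
        report = screen_all_pairs(dgi, gda)
        mesh_id = next(iter(truth.planted_pairs))[1]
        ranked = rank_for_disease(report, mesh_id, p_cutoff=1.1)
        all_for_disease = [r for r in report.results if r.mesh_id == mesh_id]
        assert len(ranked) == len(all_for_disease)
        assert [r.rank for r in ranked] == list(range(1, len(ranked) + 1))
        ps = [r.p_value for r in ranked]
        assert ps == sorted(ps)

    def test_planted_drugs_top_ranked(self):
        report, truth = self._report()
        for drug_id, mesh_id in truth.planted_pairs:
            ranked = rank_for_disease(report, mesh_id, p_cutoff=1.1)
            planted_here = {d for d, m in truth.planted_pairs if m == mesh_id}
            top = {r.drug_id for r in ranked[: len(planted_here)]}
            assert top == planted_here

    def test_unknown_disease_errors(self, small_planted):
        _, dgi, gda, _ = small_planted
        report = screen_all_pairs(dgi, gda)
        with pytest.raises(KeyError):
            rank_for_disease(report, "MESH:NOPE")


class TestEnrichmentScreenEstimator:
    def test_sklearn_param_protocol(self):
        est = EnrichmentScreen(min_overlap=2, q_cutoff=0.01)
        assert est.get_params()["min_overlap"] == 2
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(universe_mode="union")
        assert est.universe_mode == "union"

    def test_fit_populates_report(self, small_planted):
        _, dgi, gda, truth = small_planted
        est = EnrichmentScreen().fit(dgi, gda)
        assert est.report_.n_pairs_tested == len(est.results_)
        assert est.universe_size_ == len(est.universe_)
        sig = {(r.drug_id, r.mesh_id) for r in est.significant_}
        assert truth.planted_pairs <= sig

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError):
            EnrichmentScreen().score_pairs([("D", "M")])
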