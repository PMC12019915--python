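"""Running-sum enrichment score, permutation null, NES/FDR, leading edge."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ptmenrich as pe
from conftest import running_sum_oracle, signed_ks_oracle


def _ranked(scores):
    return pe.rank_proteins([(f"P{i+1}", s) for i, s in enumerate(scores)])


class TestRankProteins:
    def test_ties_broken_by_accession(self):
        ranked = pe.rank_proteins([("B", 1.0), ("A", 1.0), ("C", 2.0)])
        assert ranked.accessions == ["C", "A", "B"]

    def test_duplicates_keep_largest_magnitude(self):
        ranked = pe.rank_proteins([("A", 3.0), ("A", -5.0)])
        assert ranked.accessions == ["A"]
        assert ranked.scores[0] == -5.0
        assert "A" in ranked.duplicates

    def test_non_finite_score_names_accession(self):
        with pytest.raises(ValueError, match="'A'"):
            pe.rank_proteins([("A", float("nan"))])

    def test_scores_non_increasing(self):
        ranked = _ranked([0.3, -1.2, 5.0, 0.3])
        assert all(a >= b for a, b in zip(ranked.scores, ranked.scores[1:]))


class TestEnrichmentScore:
    def test_worked_example_weighted(self):
        ranked = _ranked([5, 4, 3, 2, 1])
        profile = pe.enrichment_score(ranked, {"P1", "P3"}, weight_p=1.0)
        expected = [5 / 8, 5 / 8 - 1 / 3, 5 / 8 - 1 / 3 + 3 / 8,
                    5 / 8 - 1 / 3 + 3 / 8 - 1 / 3, 0.0]
        assert profile.values == pytest.approx(expected, abs=1e-12)
        assert profile.peak_index == 2
        assert profile.es == pytest.approx(2 / 3)

    def test_single_top_hit_unweighted(self):
        ranked = _ranked([5, 4, 3, 2, 1])
        profile = pe.enrichment_score(ranked, {"P1"}, weight_p=0.0)
        assert profile.es == pytest.approx(1.0)
        assert profile.peak_index == 0

    def test_single_bottom_hit_unweighted(self):
        ranked = _ranked([5, 4, 3, 2, 1])
        profile = pe.enrichment_score(ranked, {"P5"}, weight_p=0.0)
        assert profile.es == pytest.approx(-1.0)
        assert profile.peak_index == 3

    def test_absent_and_full_sets_are_errors(self):
        ranked = _ranked([3, 2, 1])
        with pytest.raises(ValueError, match="absent"):
            pe.enrichment_score(ranked, {"X"})
        with pytest.raises(ValueError, match="equals"):
            pe.enrichment_score(ranked, {"P1", "P2", "P3"})

    def test_zero_weighted_hits_are_an_error(self):
        ranked = _ranked([1.0, 0.0, -1.0])
        with pytest.raises(ValueError, match="zero"):
            pe.enrichment_score(ranked, {"P2"}, weight_p=1.0)

    def test_matches_exact_oracle_small_lists(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(3, 13))
            scores = sorted(rng.integers(-9, 10, size=n).tolist(), reverse=True)
            k = int(rng.integers(1, n))
            hits = np.zeros(n, dtype=bool)
            hits[rng.choice(n, size=k, replace=False)] = True
            p = int(rng.integers(0, 3))
            if p > 0 and all(s == 0 for s, h in zip(scores, hits) if h):
                continue
            ranked = pe.RankedList(
                accessions=[f"P{i}" for i in range(n)],
                scores=np.array(scores, dtype=float),
            )
            members = {f"P{i}" for i in range(n) if hits[i]}
            profile = pe.enrichment_score(ranked, members, weight_p=float(p))
            exact_profile, exact_peak, exact_es = running_sum_oracle(
                scores, hits.tolist(), p)
            assert profile.values == pytest.approx(
                [float(v) for v in exact_profile], abs=1e-12)
            assert profile.peak_index == exact_peak
            assert profile.es == pytest.approx(float(exact_es), abs=1e-12)

    def test_unweighted_reduces_to_signed_ks(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(3, 21))
            scores = sorted(rng.integers(-20, 20, size=n).tolist(), reverse=True)
            k = int(rng.integers(1, n))
            hits = np.zeros(n, dtype=bool)
            hits[rng.choice(n, size=k, replace=False)] = True
            ranked = pe.RankedList(
                accessions=[f"P{i}" for i in range(n)],
                scores=np.array(scores, dtype=float),
            )
            members = {f"P{i}" for i in range(n) if hits[i]}
            es = pe.enrichment_score(ranked, members, weight_p=0.0).es
            assert es == pytest.approx(float(signed_ks_oracle(scores, hits.tolist())))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        n=st.integers(3, 40),
        seed=st.integers(0, 10_000),
        p=st.sampled_from([0.0, 0.5, 1.0, 2.0]),
    )
    def test_profile_ends_at_zero_and_es_bounded(self, n, seed, p):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=n))[::-1]
        k = int(rng.integers(1, n))
        members = {f"P{i+1}" for i in rng.choice(n, size=k, replace=False)}
        ranked = pe.RankedList(
            accessions=[f"P{i+1}" for i in range(n)], scores=scores)
        profile = pe.enrichment_score(ranked, members, weight_p=p)
        assert abs(profile.values[-1]) < 1e-9
        assert -1.0 - 1e-12 <= profile.es <= 1.0 + 1e-12


class TestPermutationNull:
    def test_zero_permutations_is_an_error(self):
        ranked = _ranked([3, 2, 1])
        with pytest.raises(ValueError):
            pe.permutation_null(ranked, {"P1"}, n_perm=0)

    def test_deterministic_for_fixed_seed(self):
        ranked = _ranked([4, 3, 2, 1])
        a = pe.permutation_null(ranked, {"P1", "P3"}, n_perm=50, seed=9)
        b = pe.permutation_null(ranked, {"P1", "P3"}, n_perm=50, seed=9)
        assert np.array_equal(a, b)

    def test_membership_configurations_uniform(self):
        # N=4, |S|=2: the 6 membership placements must be hit uniformly
        from ptmenrich.psea import _null_memberships

        ranked = _ranked([4, 3, 2, 1])
        draws = _null_memberships(ranked, {"P1", "P2"}, n_perm=6000, seed=5)
        configs = {c: 0 for c in itertools.combinations(range(4), 2)}
        for row in draws:
            configs[tuple(np.flatnonzero(row))] += 1
        n, p = 6000, 1 / 6
        sigma = np.sqrt(n * p * (1 - p))
        for count in configs.values():
            assert abs(count - n * p) <= 3 * sigma


class TestNesAndPvalues:
    def test_worked_example(self):
        nes, p = pe.nes_and_pvalues(0.5, [0.25, 0.25, -0.1])
        assert nes == pytest.approx(2.0)
        assert p == pytest.approx(1 / 3)

    def test_all_nulls_as_extreme(self):
        _, p = pe.nes_and_pvalues(0.5, [0.5, 0.5])
        assert p == 1.0

    def test_empty_same_sign_null_warns(self):
        with pytest.warns(pe.psea.DegenerateStatisticWarning):
            nes, p = pe.nes_and_pvalues(-0.4, [0.9, 0.9])
        assert np.isnan(nes)
        assert p == 1.0

    def test_zero_es_degenerate(self):
        with pytest.warns(pe.psea.DegenerateStatisticWarning):
            assert pe.nes_and_pvalues(0.0, [0.5]) == (0.0, 1.0)

    def test_pseudocount_keeps_p_positive(self):
        _, p = pe.nes_and_pvalues(0.9, [0.1] * 99)
        assert p == pytest.approx(1 / 100)


class TestComputeFdr:
    def test_ratio_definition_single_term(self):
        # pooled null: 4 of 100 same-sign values at least as extreme
        pool = [2.0] * 4 + [0.5] * 96
        q = pe.compute_fdr([1.5], pool)
        assert q[0] == pytest.approx(0.04)

    def test_stronger_than_every_null_gives_zero(self):
        q = pe.compute_fdr([3.0], [0.5, 1.0, -2.0])
        assert q[0] == 0.0

    def test_monotone_cleanup(self):
        # weaker term with smaller raw q drags the stronger term down
        pool = [1.2] * 10 + [0.4] * 90
        q = pe.compute_fdr([2.0, 1.0], pool)
        assert q[0] <= q[1]


class TestLeadingEdge:
    def test_positive_es_members_up_to_peak(self):
        ranked = _ranked([5, 4, 3, 2, 1])
        members = {"P1", "P3"}
        profile = pe.enrichment_score(ranked, members, weight_p=1.0)
        assert pe.leading_edge(ranked, members, profile) == ["P1", "P3"]

    def test_negative_es_members_from_peak(self):
        ranked = _ranked([5, 4, 3, 2, 1])
        profile = pe.enrichment_score(ranked, {"P5"}, weight_p=0.0)
        assert pe.leading_edge(ranked, {"P5"}, profile) == ["P5"]

    def test_all_members_before_peak_returns_all(self):
        ranked = _ranked([5, 4, 3, 2, 1])
        members = {"P1", "P2"}
        profile = pe.enrichment_score(ranked, members, weight_p=0.0)
        edge = pe.leading_edge(ranked, members, profile)
        assert edge == ["P1", "P2"]


@pytest.fixture(scope="module")
def planted():
    cfg = pe.SimulationConfig(n_proteins=150, seed=21)
    db, _ = pe.simulate_database(cfg)
    scored, truth = pe.simulate_scored_list(db, cfg)
    return db, scored, truth


class TestRunPsea:
    def test_planted_term_recovered(self, planted):
        db, scored, truth = planted
        report = pe.run_psea(db, scored, n_perm=200, seed=4)
        assert report.results[0].term == truth["enriched_term"]
        assert report.results[0].nominal_p < 0.05

    def test_deterministic_result_tables(self, planted):
        db, scored, _ = planted
        a = pe.run_psea(db, scored, n_perm=50, seed=8).to_frame()
        b = pe.run_psea(db, scored, n_perm=50, seed=8).to_frame()
        assert a.equals(b)

    def test_whole_list_term_excluded_with_warning(self):
        cfg = pe.SimulationConfig(n_proteins=20, prevalence=1.0, seed=0,
                                  terms=["Everywhere"])
        db, _ = pe.simulate_database(cfg)
        lst = [(acc, float(i)) for i, acc in enumerate(sorted(db.proteins))]
        with pytest.warns(pe.psea.DegenerateStatisticWarning):
            with pytest.raises(ValueError, match="no analyzable term"):
                pe.run_psea(db, lst, min_population_count=1, n_perm=10, seed=0)

    def test_leading_edge_subset_of_members(self, planted):
        db, scored, _ = planted
        report = pe.run_psea(db, scored, n_perm=50, seed=8)
        listed = {acc for acc, _ in scored}
        for r in report.results:
            edge = set(r.leading_edge)
            assert edge <= (db.term_index[r.term] & listed)
            if r.es != 0:
                assert edge

    def test_relabeling_invariance(self, planted):
        db, scored, _ = planted
        report_a = pe.run_psea(db, scored, n_perm=50, seed=8)

        # consistent accession relabeling across db and list
        rename = {acc: f"X{acc}" for acc in db.proteins}
        db2 = pe.AnnotationDatabase(meta=dict(db.meta))
        for acc, rec in db.proteins.items():
            new = pe.ProteinRecord(
                accession=rename[acc], organism=rec.organism,
                keywords=set(rec.keywords), ptm_terms=set(rec.ptm_terms))
            db2.proteins[rename[acc]] = new
            db2.organism_index.setdefault(rec.organism, set()).add(rename[acc])
            for t in rec.ptm_terms:
                db2.term_index.setdefault(t, set()).add(rename[acc])
        scored2 = [(rename[acc], s) for acc, s in scored]
        report_b = pe.run_psea(db2, scored2, n_perm=50, seed=8)
        for a, b in zip(report_a.results, report_b.results):
            assert a.term == b.term
            assert a.es == pytest.approx(b.es)
            assert a.nes == pytest.approx(b.nes)
            assert a.nominal_p == b.nominal_p
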