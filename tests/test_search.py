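import numpy as np
import pytest

from mirpairs import (
    CandidateSet,
    OrientedPair,
    PairStats,
    attach_significance,
    contingency_counts_bulk,
    evaluate_top_n,
    grow_combination,
    mine_stable_pairs,
    pair_coverage,
    rank_by_frequency,
    select_candidates,
    select_classifier,
)

from conftest import make_matrix, random_matrix
from oracles import brute_coverage, greedy_trace_oracle


def case_matrix_from_coverage(coverage: dict[str, set[str]], sample_ids: list[str]):
    """Build a case matrix in which pair ('a_i','b_i') is reversed exactly on
    the given samples: put each pair on its own pair of miRNA rows."""
    mirnas, rows = [], []
    for name, covered in coverage.items():
        a, b = f"{name}_a", f"{name}_b"
        mirnas += [a, b]
        rows.append([1.0 if s in covered else 2.0 for s in sample_ids])  # a
        rows.append([1.5] * len(sample_ids))  # b: a<b iff a==1.0
    return make_matrix(np.array(rows), mirna_ids=mirnas, sample_ids=sample_ids)


def make_candidates(coverage: dict[str, set[str]], qs: dict[str, float], n_cases: int):
    stats = []
    for name, covered in coverage.items():
        m2 = len(covered)
        stats.append(
            PairStats(
                OrientedPair(f"{name}_a", f"{name}_b"),
                n1=99, n2=1, m1=n_cases - m2, m2=m2,
                p_value=qs[name] / 10, q_value=qs[name],
            )
        )
    return CandidateSet(tuple(stats), q_threshold=0.05, reversal_threshold=0.0)


class TestPairCoverage:
    def test_fully_reversed_pair_covers_all(self):
        cases = make_matrix([[1.0] * 4, [2.0] * 4], mirna_ids=["a", "b"])
        assert pair_coverage(OrientedPair("a", "b"), cases) == frozenset(cases.sample_ids)

    def test_never_reversed_pair_covers_none(self):
        cases = make_matrix([[2.0] * 4, [1.0] * 4], mirna_ids=["a", "b"])
        assert pair_coverage(OrientedPair("a", "b"), cases) == frozenset()

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_per_sample_loop(self, seed):
        rng = np.random.default_rng(seed)
        cases = random_matrix(rng, 2, 15)
        pair = OrientedPair(*cases.mirna_ids)
        assert pair_coverage(pair, cases) == brute_coverage(pair, cases)


class TestGrowCombination:
    def test_hand_traced_greedy_example(self):
        # 4 cases; P1 covers {s1,s2,s3}, P2 covers {s3,s4}, P3 covers {s4}
        sample_ids = ["s1", "s2", "s3", "s4"]
        coverage = {"P1": {"s1", "s2", "s3"}, "P2": {"s3", "s4"}, "P3": {"s4"}}
        cases = case_matrix_from_coverage(coverage, sample_ids)
        cands = make_candidates(coverage, {"P1": 0.01, "P2": 0.02, "P3": 0.03}, 4)
        pivot = next(s for s in cands if s.pair.a == "P1_a")
        comb = grow_combination(pivot, cands, cases)
        assert [m.pair.a for m in comb.members] == ["P1_a", "P2_a"]
        assert comb.coverage == 1.0

    def test_pivot_covering_everything_stays_alone(self):
        sample_ids = ["s1", "s2"]
        coverage = {"P1": {"s1", "s2"}, "P2": {"s1"}}
        cases = case_matrix_from_coverage(coverage, sample_ids)
        cands = make_candidates(coverage, {"P1": 0.01, "P2": 0.02}, 2)
        pivot = next(s for s in cands if s.pair.a == "P1_a")
        comb = grow_combination(pivot, cands, cases)
        assert len(comb.members) == 1 and comb.coverage == 1.0

    def test_equal_gain_tie_broken_by_smaller_q(self):
        sample_ids = ["s1", "s2", "s3"]
        coverage = {"P1": {"s1"}, "P2": {"s2", "s3"}, "P3": {"s2", "s3"}}
        cases = case_matrix_from_coverage(coverage, sample_ids)
        cands = make_candidates(coverage, {"P1": 0.01, "P2": 0.04, "P3": 0.02}, 3)
        pivot = next(s for s in cands if s.pair.a == "P1_a")
        comb = grow_combination(pivot, cands, cases)
        assert [m.pair.a for m in comb.members] == ["P1_a", "P3_a"]

    def test_intersection_mode_never_grows(self):
        sample_ids = ["s1", "s2", "s3"]
        coverage = {"P1": {"s1", "s2"}, "P2": {"s2", "s3"}}
        cases = case_matrix_from_coverage(coverage, sample_ids)
        cands = make_candidates(coverage, {"P1": 0.01, "P2": 0.02}, 3)
        pivot = next(s for s in cands if s.pair.a == "P1_a")
        comb = grow_combination(pivot, cands, cases, mode="intersection")
        assert len(comb.members) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_trace_matches_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_cases, n_pairs = 12, 8
        sample_ids = [f"s{j}" for j in range(n_cases)]
        coverage = {
            f"P{i}": {s for s in sample_ids if rng.random() < 0.4} for i in range(n_pairs)
        }
        coverage = {k: v for k, v in coverage.items() if v}
        if not coverage:
            return
        qs = {k: float(q) for k, q in zip(coverage, rng.uniform(0.001, 0.04, len(coverage)))}
        cases = case_matrix_from_coverage(coverage, sample_ids)
        cands = make_candidates(coverage, qs, n_cases)
        tie_order = [s.pair.key for s in sorted(cands, key=lambda s: (s.q_value, s.pair.a))]
        cov_by_key = {s.pair.key: coverage[s.pair.a[:-2]] for s in cands}
        for pivot in cands:
            comb = grow_combination(pivot, cands, cases)
            members, covered = greedy_trace_oracle(pivot.pair.key, cov_by_key, tie_order)
            assert [m.pair.key for m in comb.members] == members
            assert comb.coverage == pytest.approx(len(covered) / n_cases)
            assert comb.coverage >= len(cov_by_key[pivot.pair.key]) / n_cases

    def test_pivot_must_be_a_candidate(self):
        sample_ids = ["s1"]
        coverage = {"P1": {"s1"}}
        cases = case_matrix_from_coverage(coverage, sample_ids)
        cands = make_candidates(coverage, {"P1": 0.01}, 1)
        outsider = PairStats(OrientedPair("zz_a", "zz_b"), 9, 1, 1, 9, q_value=0.01)
        with pytest.raises(ValueError, match="pivot"):
            grow_combination(outsider, cands, cases)


class TestRankByFrequency:
    def test_counts_and_order(self):
        sample_ids = ["s1", "s2"]
        coverage = {"X": {"s1"}, "Y": {"s2"}}
        cases = case_matrix_from_coverage(coverage, sample_ids)
        cands = make_candidates(coverage, {"X": 0.01, "Y": 0.02}, 2)
        combos = [grow_combination(p, cands, cases) for p in cands]
        ranked = rank_by_frequency(combos)
        # X and Y each appear in both combinations (each compensates the other)
        assert [(e[0].pair.a, e[1]) for e in ranked.entries] == [("X_a", 2), ("Y_a", 2)]

    def test_self_covering_pivots_all_frequency_one(self):
        sample_ids = ["s1", "s2", "s3"]
        coverage = {"B": {"s1", "s2", "s3"}, "A": {"s1", "s2", "s3"}}
        cases = case_matrix_from_coverage(coverage, sample_ids)
        cands = make_candidates(coverage, {"A": 0.01, "B": 0.01}, 3)
        ranked = rank_by_frequency([grow_combination(p, cands, cases) for p in cands])
        assert [e[1] for e in ranked.entries] == [1, 1]
        # frequency tie with equal q: lexicographic order of pair ids
        assert [e[0].pair.a for e in ranked.entries] == ["A_a", "B_a"]

    def test_empty_input(self):
        assert len(rank_by_frequency([])) == 0


class TestEvaluateAndSelect:
    def build(self, coverage, qs, sample_ids, control_ids):
        cases = case_matrix_from_coverage(coverage, sample_ids)
        # controls: every pair conforming (a=2.0 > b=1.5)
        controls = make_matrix(
            np.array([[2.0] * len(control_ids), [1.5] * len(control_ids)] * len(coverage)).reshape(
                2 * len(coverage), len(control_ids)
            ),
            mirna_ids=cases.mirna_ids,
            sample_ids=control_ids,
        )
        cands = make_candidates(coverage, qs, len(sample_ids))
        ranked = rank_by_frequency([grow_combination(p, cands, cases) for p in cands])
        return ranked, cases, controls

    def test_perfect_single_pair_scores_one(self):
        ranked, cases, controls = self.build(
            {"P": {"s1", "s2", "s3"}}, {"P": 0.01}, ["s1", "s2", "s3"], ["c1", "c2"]
        )
        assert evaluate_top_n(ranked, 1, cases, controls) == 1.0

    def test_even_n_rejected(self):
        ranked, cases, controls = self.build(
            {"P": {"s1"}, "Q": {"s1"}}, {"P": 0.01, "Q": 0.02}, ["s1"], ["c1"]
        )
        with pytest.raises(ValueError, match="odd"):
            evaluate_top_n(ranked, 2, cases, controls)

    def test_smallest_maximizer_chosen(self, recovery_cohorts):
        controls, cases, truth = recovery_cohorts
        stable = mine_stable_pairs(controls, 0.95)
        stats = attach_significance(contingency_counts_bulk(list(stable), controls, cases))
        cands = select_candidates(stats)
        combos = [grow_combination(p, cands, cases) for p in cands]
        ranked = rank_by_frequency(combos)
        report = select_classifier(ranked, cases, controls, max_top=31)
        indices = dict(report.indices)
        best = max(indices.values())
        assert indices[report.chosen_n] == best
        assert all(n >= report.chosen_n for n, v in indices.items() if v == best)
        assert len(report.classifier) == report.chosen_n

    def test_single_ranked_pair_forces_n_one(self):
        ranked, cases, controls = self.build(
            {"P": {"s1", "s2"}}, {"P": 0.01}, ["s1", "s2"], ["c1", "c2"]
        )
        report = select_classifier(ranked, cases, controls)
        assert report.chosen_n == 1

    def test_search_is_deterministic(self, recovery_cohorts):
        controls, cases, _ = recovery_cohorts
        stable = mine_stable_pairs(controls, 0.95)
        stats = attach_significance(contingency_counts_bulk(list(stable), controls, cases))
        cands = select_candidates(stats)

        def run():
            combos = [grow_combination(p, cands, cases) for p in cands]
            ranked = rank_by_frequency(combos)
            report = select_classifier(ranked, cases, controls)
            return [(p.a, p.b) for p in report.classifier.pairs], report.indices

        assert run() == run()
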