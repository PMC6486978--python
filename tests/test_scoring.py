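"""GSZ scoring, hypergeometric enrichment, and expression preprocessing."""
from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tristate import (
    ContractViolation,
    expression_by_state,
    gsz_score,
    hypergeometric_enrichment,
    quantile_normalize,
    rpkm_log,
)
from tristate.scoring import read_gmt, set_vs_stable_expression
from tristate.states import TransitionSet


class TestGsz:
    def test_constant_universe_scores_zero(self):
        v = pd.Series(3.0, index=[f"g{i}" for i in range(10)])
        assert gsz_score(v, {"g0", "g1"}) == 0.0

    def test_hand_computed_binary_example(self):
        # universe {1,1,0,0,0,0}, set = the two 1-genes:
        # mu = 1/3, sigma^2 = 2/9, numerator 4/3, denominator sqrt(16/45)
        v = pd.Series([1, 1, 0, 0, 0, 0], index=list("abcdef"), dtype=float)
        assert gsz_score(v, {"a", "b"}) == pytest.approx(math.sqrt(5.0))

    def test_whole_universe_set_is_degenerate_zero(self):
        v = pd.Series(np.arange(6, dtype=float), index=list("abcdef"))
        assert gsz_score(v, set("abcdef")) == 0.0

    def test_small_set_rejected(self):
        v = pd.Series(np.arange(6, dtype=float), index=list("abcdef"))
        with pytest.raises(ContractViolation, match="minimum"):
            gsz_score(v, {"a"})
        with pytest.raises(ContractViolation):
            gsz_score(v, {"zz", "yy"})  # disjoint from universe

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=30, unique=True),
           st.data())
    def test_antisymmetric_under_value_negation(self, values, data):
        idx = [f"g{i}" for i in range(len(values))]
        v = pd.Series(values, index=idx)
        m = data.draw(st.integers(2, len(values) - 1))
        subset = set(idx[:m])
        assert gsz_score(-v, subset) == pytest.approx(-gsz_score(v, subset),
                                                      abs=1e-9)

    def test_permutation_null_moments(self):
        # under random same-size sets the score has mean 0 and SD 1 exactly
        # (sampling-without-replacement standardization); empirical check
        rng = np.random.default_rng(2024)
        v = pd.Series(rng.normal(size=500), index=[f"g{i}" for i in range(500)])
        scores = []
        for _ in range(2000):
            pick = rng.choice(500, size=40, replace=False)
            scores.append(gsz_score(v, set(v.index[pick])))
        assert abs(np.mean(scores)) < 0.05
        assert 0.9 < np.std(scores) < 1.1


class TestHypergeometric:
    def test_zero_overlap_has_p_one(self):
        r = hypergeometric_enrichment({"a", "b"}, {"c", "d"}, set("abcdef"))
        assert r.p_value == 1.0 and r.overlap == 0 and r.direction == "under"

    def test_exact_worked_example(self):
        # N=10, K=5, n=4, k=4: p = C(5,4)/C(10,4) = 5/210
        universe = {f"g{i}" for i in range(10)}
        annotation = {f"g{i}" for i in range(5)}
        r = hypergeometric_enrichment(annotation - {"g4"} | {"g0", "g1", "g2", "g3"},
                                      annotation, universe)
        r = hypergeometric_enrichment({"g0", "g1", "g2", "g3"}, annotation, universe)
        assert r.overlap == 4
        assert r.p_value == pytest.approx(5 / 210)
        assert r.expected == pytest.approx(4 * 5 / 10)

    def test_monotone_decreasing_in_overlap(self):
        universe = [f"g{i}" for i in range(40)]
        annotation = set(universe[:15])
        ps = []
        # fixed draw size n=10 with k genes from the annotation
        for k in range(0, 11):
            gene_set = set(universe[:k]) | set(universe[15:25 - k])
            r = hypergeometric_enrichment(gene_set, annotation, set(universe))
            assert r.set_size == 10 and r.overlap == k
            ps.append(r.p_value)
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_matches_exhaustive_enumeration_small_universe(self):
        universe = list("abcdefghij")  # N = 10
        annotation = set("abcd")
        gene_set = set("abce")
        k_obs = len(gene_set & annotation)
        total = hits = 0
        for draw in itertools.combinations(universe, len(gene_set)):
            total += 1
            hits += len(set(draw) & annotation) >= k_obs
        r = hypergeometric_enrichment(gene_set, annotation, set(universe))
        assert r.p_value == pytest.approx(hits / total)

    def test_empty_universe_rejected(self):
        with pytest.raises(ContractViolation):
            hypergeometric_enrichment({"a"}, {"a"}, set())


class TestRpkm:
    def test_worked_arithmetic(self):
        counts = pd.Series({"g1": 10})
        out = rpkm_log(counts, {"g1": 2000}, library_size=1e6)
        assert out["g1"] == pytest.approx(math.log2(6))  # RPKM 5 -> log2(5+1)

    def test_zero_count_maps_to_zero(self):
        out = rpkm_log(pd.Series({"g1": 0}), {"g1": 500}, library_size=1e6)
        assert out["g1"] == 0.0

    def test_round_trip_recovers_counts(self):
        rng = np.random.default_rng(1)
        counts = pd.Series(rng.integers(0, 5000, size=100).astype(float),
                           index=[f"g{i}" for i in range(100)])
        lengths = {g: float(rng.integers(300, 20000)) for g in counts.index}
        lib = 2.5e7
        out = rpkm_log(counts, lengths, library_size=lib)
        back = (2.0 ** out - 1) * pd.Series(lengths) / 1e3 * (lib / 1e6)
        assert np.allclose(back.sort_index(), counts.sort_index())

    def test_missing_length_rejected(self):
        with pytest.raises(ContractViolation):
            rpkm_log(pd.Series({"g1": 5}), {}, library_size=1e6)


class TestQuantileNormalize:
    def test_identical_columns_are_a_fixed_point(self):
        m = pd.DataFrame({"s1": [5.0, 1.0, 3.0], "s2": [5.0, 1.0, 3.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_hand_computed_two_columns(self):
        m = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        assert out["s1"].tolist() == [2.5, 3.5, 4.5]
        assert out["s2"].tolist() == [2.5, 3.5, 4.5]

    def test_columns_share_sorted_values_and_idempotence(self):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(rng.normal(size=(50, 4)),
                         columns=list("abcd"))
        out = quantile_normalize(m)
        ref = np.sort(out["a"].to_numpy())
        for c in "bcd":
            assert np.allclose(np.sort(out[c].to_numpy()), ref)
        again = quantile_normalize(out)
        assert np.allclose(again.to_numpy(), out.to_numpy(), atol=1e-12)

    def test_ties_get_average_rank_value(self):
        m = pd.DataFrame({"s1": [1.0, 1.0, 3.0], "s2": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        assert out["s1"][0] == out["s1"][1]
        # tied pair sits at rank 1.5: mean of the rank-1 and rank-2 means
        means = [(1 + 2) / 2, (1 + 4) / 2, (3 + 6) / 2]
        assert out["s1"][0] == pytest.approx((means[0] + means[1]) / 2)

    def test_detection_filter(self):
        m = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]},
                         index=["g1", "g2", "g3"])
        p = pd.DataFrame({"s1": [0.5, 0.01, 0.5], "s2": [0.5, 0.5, 0.04]},
                         index=["g1", "g2", "g3"])
        out = quantile_normalize(m, detection_p=p)
        assert list(out.index) == ["g2", "g3"]
        with pytest.raises(ContractViolation):
            quantile_normalize(m, detection_p=p, p_cut=1e-6)

    def test_single_sample_rejected(self):
        with pytest.raises(ContractViolation):
            quantile_normalize(pd.DataFrame({"s1": [1.0, 2.0]}))


class TestExpressionByState:
    def test_single_state_summary(self):
        states = pd.Series({"g1": "100", "g2": "100"}, dtype=str)
        expr = pd.Series({"g1": 2.0, "g2": 4.0})
        out = expression_by_state(states, expr)
        assert len(out) == 1
        assert out.at["100", "mean"] == 3.0 and out.at["100", "n"] == 2

    def test_no_overlap_rejected(self):
        with pytest.raises(ContractViolation):
            expression_by_state(pd.Series({"g1": "100"}, dtype=str),
                                pd.Series({"g2": 1.0}))

    def test_set_vs_stable_reference_states(self):
        a = pd.Series({"g1": "100", "g2": "100", "g3": "101"}, dtype=str)
        b = pd.Series({"g1": "101", "g2": "100", "g3": "101"}, dtype=str)
        expr = pd.Series({"g1": 5.0, "g2": 3.0, "g3": 8.0})
        tset = TransitionSet("100->101", frozenset({"g1"}))
        out = set_vs_stable_expression(tset, a, b, expr)
        assert out.at["100->101", "mean"] == 5.0
        assert out.at["stable 100", "mean"] == 3.0
        assert out.at["stable 101", "mean"] == 8.0


def test_read_gmt(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("dna_repair\tdesc\tg1\tg2\tg3\nribosome\t\tg4\n")
    sets = read_gmt(p)
    assert sets == {"dna_repair": {"g1", "g2", "g3"}, "ribosome": {"g4"}}
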