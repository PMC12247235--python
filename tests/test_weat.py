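import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle
from medbias.errors import DegenerateEmbeddingError, ZeroVarianceError
from medbias.synth import make_synthetic_benchmark, table_for_benchmark
from medbias.weat import (
    WeatConfig,
    WeatInputs,
    association,
    cosine,
    effect_size,
    pairwise_weat,
    permutation_p,
    run_weat,
    weat_statistic,
)

SQRT2_OVER_2 = math.sqrt(2) / 2


class TestCosine:
    def test_orthogonal(self):
        assert cosine((1, 0), (0, 1)) == pytest.approx(0.0)

    def test_parallel(self):
        assert cosine((1, 0), (1, 0)) == pytest.approx(1.0)

    def test_analytic_45_degrees(self):
        assert cosine((1, 1), (1, 0)) == pytest.approx(SQRT2_OVER_2)

    def test_zero_norm_error(self):
        with pytest.raises(DegenerateEmbeddingError):
            cosine((0, 0), (1, 0))

    def test_scale_invariant(self):
        assert cosine((2, 3), (5, -1)) == pytest.approx(cosine((20, 30), (0.5, -0.1)))


class TestAssociation:
    def test_identical_attribute_sets_zero(self, rng):
        A = rng.standard_normal((3, 4))
        w = rng.standard_normal(4)
        assert association(w, A, A) == pytest.approx(0.0)

    def test_simple_separation(self):
        assert association((1, 0), [(1, 0)], [(0, 1)]) == pytest.approx(1.0)

    def test_derived_example(self):
        # cos((0.8,0.6),(1,0)) - cos((0.8,0.6),(0,1)) = 0.8 - 0.6
        got = association((0.8, 0.6), [(1, 0)], [(0, 1)])
        assert got == pytest.approx(0.2)
        assert got == pytest.approx(oracle.assoc((0.8, 0.6), [(1, 0)], [(0, 1)]))

    def test_antisymmetric_in_AB(self, rng):
        A, B = rng.standard_normal((3, 4)), rng.standard_normal((2, 4))
        w = rng.standard_normal(4)
        assert association(w, A, B) == pytest.approx(-association(w, B, A))


class TestStatistic:
    def test_equal_targets_zero(self, rng):
        X = rng.standard_normal((3, 4))
        inp = WeatInputs(X, X, rng.standard_normal((2, 4)), rng.standard_normal((2, 4)))
        assert weat_statistic(inp) == pytest.approx(0.0)

    def test_toy_value(self, toy_inputs):
        # s-values {1, 0.2} vs {-1, -0.2}
        assert weat_statistic(toy_inputs) == pytest.approx(2.4)

    def test_swap_attributes_negates(self, toy_inputs):
        assert weat_statistic(toy_inputs.swapped_attributes()) == pytest.approx(-2.4)


class TestEffectSize:
    def test_perfect_separation_is_two(self):
        # X aligned with A's direction, Y with B's, orthogonal directions
        inp = WeatInputs(
            X=[(1, 0), (1, 0)], Y=[(0, 1), (0, 1)], A=[(1, 0)], B=[(0, 1)]
        )
        assert effect_size(inp) == pytest.approx(2.0)

    def test_toy_value(self, toy_inputs):
        # mean diff 1.2 over population sd sqrt(0.52)
        assert effect_size(toy_inputs) == pytest.approx(1.2 / math.sqrt(0.52))
        assert effect_size(toy_inputs) == pytest.approx(1.6641005886756874)

    def test_swap_targets_negates(self, toy_inputs):
        assert effect_size(toy_inputs.swapped_targets()) == pytest.approx(-effect_size(toy_inputs))

    def test_zero_variance_error(self):
        inp = WeatInputs(X=[(1, 0)], Y=[(1, 0)], A=[(1, 0)], B=[(0, 1)])
        with pytest.raises(ZeroVarianceError):
            effect_size(inp)

    def test_sample_sd_switch(self, toy_inputs):
        pop = effect_size(toy_inputs, sd="population")
        smp = effect_size(toy_inputs, sd="sample")
        assert smp == pytest.approx(pop * math.sqrt(3 / 4))


class TestPermutationP:
    def test_toy_exhaustive_zero(self, toy_inputs):
        p, n, mode, ties = permutation_p(toy_inputs, mode="exhaustive")
        assert (p, n, mode) == (0.0, 6, "exhaustive")

    def test_observed_at_s_zero(self):
        # partition whose statistic is 0: two larger S values out of 6
        inp = WeatInputs(
            X=[(1.0, 0.0), (0.0, 1.0)], Y=[(0.8, 0.6), (0.6, 0.8)], A=[(1, 0)], B=[(0, 1)]
        )
        p, n, _, _ = permutation_p(inp, mode="exhaustive")
        assert p == pytest.approx(2 / 6)

    def test_equal_attribute_sets_degenerate_edge(self, rng):
        X, Y = rng.standard_normal((2, 3)), rng.standard_normal((2, 3))
        A = rng.standard_normal((2, 3))
        p, _, _, ties = permutation_p(WeatInputs(X, Y, A, A), mode="exhaustive")
        assert p == 0.0 and ties == 1.0  # every partition has S = 0

    def test_unequal_sizes_error(self, rng):
        inp = WeatInputs(rng.standard_normal((2, 3)), rng.standard_normal((3, 3)),
                         rng.standard_normal((2, 3)), rng.standard_normal((2, 3)))
        with pytest.raises(ValueError):
            permutation_p(inp)

    def test_mc_too_few_draws(self, toy_inputs):
        with pytest.raises(ValueError):
            permutation_p(toy_inputs, mode="monte-carlo", n_draws=50)

    def test_mc_seeded_reproducible(self, rng):
        from tests_util import random_weat_inputs

        inp = random_weat_inputs(rng, n=6, dim=8)
        a = permutation_p(inp, mode="monte-carlo", n_draws=500, seed=42)
        b = permutation_p(inp, mode="monte-carlo", n_draws=500, seed=42)
        assert a == b

    def test_mc_agrees_with_exhaustive(self, rng):
        from tests_util import random_weat_inputs

        inp = random_weat_inputs(rng, n=4, dim=8)
        p_ex, *_ = permutation_p(inp, mode="exhaustive")
        p_mc, *_ = permutation_p(inp, mode="monte-carlo", n_draws=20_000, seed=7)
        assert p_mc == pytest.approx(p_ex, abs=0.02)

    def test_auto_picks_exhaustive_for_small(self, toy_inputs):
        _, n, mode, _ = permutation_p(toy_inputs, mode="auto")
        assert mode == "exhaustive" and n == 6

    def test_complementarity(self, rng):
        from tests_util import random_weat_inputs

        for _ in range(10):
            inp = random_weat_inputs(rng, n=3, dim=6)
            p_ab, n, _, ties_ab = permutation_p(inp, mode="exhaustive")
            p_ba, _, _, ties_ba = permutation_p(inp.swapped_attributes(), mode="exhaustive")
            assert ties_ab == ties_ba
            assert p_ab + p_ba == pytest.approx(1.0 - ties_ab)


class TestOracleEquivalence:
    def test_matches_brute_force(self, rng):
        from tests_util import random_weat_inputs

        for trial in range(25):
            n = int(rng.integers(2, 5))
            inp = random_weat_inputs(rng, n=n, m=int(rng.integers(1, 4)), dim=6)
            X, Y, A, B = inp.X.tolist(), inp.Y.tolist(), inp.A.tolist(), inp.B.tolist()
            assert weat_statistic(inp) == pytest.approx(oracle.statistic(X, Y, A, B), abs=1e-10)
            assert effect_size(inp) == pytest.approx(oracle.effect_size(X, Y, A, B), abs=1e-10)
            greater, _, total = oracle.exhaustive_permutation(X, Y, A, B)
            p, n_used, _, _ = permutation_p(inp, mode="exhaustive")
            assert n_used == total
            assert p == pytest.approx(greater / total)


# hypothesis strategies ------------------------------------------------------

def _vector_sets(draw, n, m, dim):
    elems = st.floats(-5, 5, allow_nan=False, width=32)
    mk = lambda k: draw(
        st.lists(st.lists(elems, min_size=dim, max_size=dim), min_size=k, max_size=k)
    )
    return mk(n), mk(n), mk(m), mk(m)


@st.composite
def weat_inputs(draw):
    n = draw(st.integers(2, 4))
    m = draw(st.integers(1, 3))
    dim = draw(st.integers(2, 6))
    X, Y, A, B = _vector_sets(draw, n, m, dim)
    for mat in (X, Y, A, B):
        for v in mat:
            if not any(abs(c) > 1e-3 for c in v):
                v[0] = 1.0
    return WeatInputs(X, Y, A, B)


def _nondegenerate(inp, min_sigma=0.0):
    """Reject zero-variance inputs (and, for invariance checks, near-zero
    variance where cancellation makes the effect size ill-conditioned)."""
    from medbias.weat import association_profile

    try:
        effect_size(inp)
    except ZeroVarianceError:
        return False
    sx, sy = association_profile(inp)
    return float(np.std(np.concatenate([sx, sy]))) > min_sigma


def _min_partition_gap(inp):
    """Smallest gap between distinct partition statistics (exhaustive)."""
    import itertools

    from medbias.weat import association_profile

    s_all = np.concatenate(association_profile(inp))
    total = s_all.sum()
    n = inp.X.shape[0]
    values = sorted(
        2.0 * s_all[list(c)].sum() - total
        for c in itertools.combinations(range(2 * n), n)
    )
    return min(b - a for a, b in zip(values, values[1:]))


class TestProperties:
    @settings(max_examples=60, deadline=None)
    @given(weat_inputs())
    def test_antisymmetry_and_bound(self, inp):
        if not _nondegenerate(inp):
            return
        d = effect_size(inp)
        assert abs(d) <= 2.0 + 1e-12
        assert effect_size(inp.swapped_targets()) == pytest.approx(-d)
        assert effect_size(inp.swapped_attributes()) == pytest.approx(-d)
        s = weat_statistic(inp)
        assert weat_statistic(inp.swapped_targets()) == pytest.approx(-s)
        assert weat_statistic(inp.swapped_attributes()) == pytest.approx(-s)

    @settings(max_examples=30, deadline=None)
    @given(weat_inputs(), st.floats(0.1, 10), st.integers(0, 2**31 - 1))
    def test_scale_and_rotation_invariance(self, inp, scale, rot_seed):
        if not _nondegenerate(inp, min_sigma=1e-6):
            return
        dim = inp.X.shape[1]
        q, _ = np.linalg.qr(np.random.default_rng(rot_seed).standard_normal((dim, dim)))
        tf = lambda M: scale * (M @ q.T)
        out = WeatInputs(tf(inp.X), tf(inp.Y), tf(inp.A), tf(inp.B))
        assert effect_size(out) == pytest.approx(effect_size(inp), abs=1e-9)
        assert weat_statistic(out) == pytest.approx(weat_statistic(inp), abs=1e-9)
        # the strict-inequality p is only rotation-stable when no two
        # partition statistics are close enough for float noise to reorder
        if _min_partition_gap(inp) > 1e-6:
            p0, *_ = permutation_p(inp, mode="exhaustive")
            p1, *_ = permutation_p(out, mode="exhaustive")
            assert p0 == p1


class TestRunWeat:
    def test_planted_bias_extreme(self, syn_benchmark, planted_table):
        res = run_weat(syn_benchmark, planted_table, config=WeatConfig(mode="exhaustive"))
        assert res.effect_size > 1.5
        assert res.p_value <= 1 / 100

    def test_null_table_not_extreme(self, syn_benchmark):
        from medbias.synth import table_for_benchmark

        rejected = 0
        for seed in range(20):
            table = table_for_benchmark(syn_benchmark, beta=0.0, seed=seed)
            res = run_weat(syn_benchmark, table, config=WeatConfig(mode="exhaustive"))
            rejected += res.p_value < 0.05
        assert rejected <= 4  # a 0.05-level test should rarely fire under the null

    def test_group_order_negates(self, syn_benchmark, planted_table):
        r12 = run_weat(syn_benchmark, planted_table, group_pair=("grp1", "grp2"))
        r21 = run_weat(syn_benchmark, planted_table, group_pair=("grp2", "grp1"))
        assert r21.effect_size == pytest.approx(-r12.effect_size)

    def test_result_provenance(self, syn_benchmark, planted_table):
        res = run_weat(syn_benchmark, planted_table, config=WeatConfig(mode="exhaustive"))
        assert res.benchmark == "SYN"
        assert (res.a_label, res.b_label) == ("grp1", "grp2")
        assert res.mode == "exhaustive"


class TestPairwise:
    def test_three_groups_six_results(self):
        ds = make_synthetic_benchmark(n_targets=4, n_attributes_per_group=3, n_groups=3)
        table = table_for_benchmark(ds, beta=4.0, seed=2)
        results = pairwise_weat(ds, table, config=WeatConfig(mode="exhaustive"))
        assert len(results) == 6
        pairs = {(r.a_label, r.b_label) for r in results}
        assert len(pairs) == 6

    def test_ordered_pairs_negate(self):
        ds = make_synthetic_benchmark(n_targets=4, n_attributes_per_group=3, n_groups=3)
        table = table_for_benchmark(ds, beta=4.0, seed=2)
        results = {(r.a_label, r.b_label): r for r in pairwise_weat(ds, table)}
        for (a, b), r in results.items():
            assert results[(b, a)].effect_size == pytest.approx(-r.effect_size)

    def test_two_groups_two_results(self, syn_benchmark, planted_table):
        assert len(pairwise_weat(syn_benchmark, planted_table)) == 2

    def test_single_group_error(self, planted_table):
        ds = make_synthetic_benchmark(n_groups=1)
        with pytest.raises(ValueError):
            pairwise_weat(ds, planted_table)
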