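import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from convar.backbone import ResponseStack
from convar.errors import ContractError, GridError
from convar.measures import (
    GRID_SIZES,
    MaxPoolMap,
    feature_names,
    feature_vector,
    max_pool_map,
    normalize_histograms,
    p_a,
    p_f,
    p_g,
    self_similarity,
)
from conftest import BATTERY_SEEDS, random_stack


# ------------------------------------------------------- naive reference path

def naive_max_pool(resp, n):
    """Brute-force per-subregion maxima with the round(j*size/n) boundaries."""
    k, h, w = resp.shape
    rb = [int(np.floor(j * h / n + 0.5)) for j in range(n + 1)]
    cb = [int(np.floor(j * w / n + 0.5)) for j in range(n + 1)]
    out = np.empty((n, n, k))
    for x in range(n):
        for y in range(n):
            for i in range(k):
                out[x, y, i] = resp[i, rb[x] : rb[x + 1], cb[y] : cb[y + 1]].max()
    return out


def naive_var(values):
    vals = list(values)
    mean = sum(vals) / len(vals)
    return sum((v - mean) ** 2 for v in vals) / len(vals)


def naive_pa(m):
    return naive_var(m.flatten().tolist())


def naive_pg(m):
    n = m.shape[0]
    return float(np.median([naive_var(m[x, y, :]) for x in range(n) for y in range(n)]))


def naive_pf(m):
    k = m.shape[2]
    return float(np.median([naive_var(m[:, :, i].flatten()) for i in range(k)]))


def _map_from(values, normalized=False):
    return MaxPoolMap(layer_id=1, grid=values.shape[0], values=values, normalized=normalized)


class TestMaxPoolMap:
    def test_two_by_two_blocks(self):
        resp = ResponseStack(1, np.arange(1.0, 17.0).reshape(1, 4, 4))
        m = max_pool_map(resp, 2)
        assert np.array_equal(m.values[:, :, 0], [[6, 8], [14, 16]])

    def test_constant_map(self):
        m = max_pool_map(ResponseStack(1, np.full((3, 8, 8), 2.5)), 4)
        assert np.all(m.values == 2.5)

    def test_global_maximum_at_n1(self):
        stack = random_stack(0)
        m = max_pool_map(stack, 1)
        assert np.allclose(m.values[0, 0], stack.responses.max(axis=(1, 2)))

    def test_grid_too_large(self):
        with pytest.raises(GridError):
            max_pool_map(random_stack(0, h=6, w=6), 7)

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_uneven_division_matches_bruteforce(self, n):
        stack = random_stack(1, k=3, h=7, w=11)
        assert np.array_equal(max_pool_map(stack, n).values, naive_max_pool(stack.responses, n))


class TestNormalizeHistograms:
    def test_l1_normalization(self):
        m = normalize_histograms(_map_from(np.array([[[2.0, 6.0]]])))
        assert np.allclose(m.values, [[[0.25, 0.75]]])

    def test_idempotent(self):
        m = normalize_histograms(_map_from(np.random.default_rng(0).random((3, 3, 4))))
        again = normalize_histograms(m)
        assert again.normalized and np.array_equal(again.values, m.values)

    def test_zero_subregion_uniform_fill(self):
        v = np.zeros((2, 2, 4))
        v[0, 0] = [1, 2, 3, 4]
        m = normalize_histograms(_map_from(v))
        assert np.allclose(m.values[1, 1], 0.25)
        assert np.allclose(m.values.sum(axis=2), 1.0)

    def test_negative_entries_rejected(self):
        with pytest.raises(ContractError):
            normalize_histograms(_map_from(np.array([[[1.0, -0.5]]])))


def _all_ones_zero_map():
    """Four subregions, k=2, every histogram (1, 0)."""
    v = np.zeros((2, 2, 2))
    v[:, :, 0] = 1.0
    return _map_from(v, normalized=True)


class TestVarianceMeasures:
    def test_pa_zero_on_uniform_histograms(self):
        # identical uniform histograms: zero up to float representation of 1/k
        m = _map_from(np.full((3, 3, 5), 0.2), normalized=True)
        assert p_a(m) <= 1e-30
        m2 = _map_from(np.full((4, 4, 2), 0.5), normalized=True)
        assert p_a(m2) == 0.0  # 1/2 is exactly representable

    def test_pa_hand_value(self):
        # entries {1,0,1,0,1,0,1,0}: population variance 0.25
        assert p_a(_all_ones_zero_map()) == pytest.approx(0.25)

    def test_pg_hand_value(self):
        assert p_g(_all_ones_zero_map()) == pytest.approx(0.25)

    def test_pg_median_with_mixed_subregions(self):
        v = np.zeros((2, 2, 2))
        v[:, :, 0] = 1.0
        v[1, 1] = [0.5, 0.5]
        assert p_g(_map_from(v, normalized=True)) == pytest.approx(0.25)

    def test_pf_zero_when_filters_spatially_constant(self):
        assert p_f(_all_ones_zero_map()) == 0.0

    def test_pf_hand_value_alternating(self):
        v = np.array(
            [[[1.0, 0.0], [0.0, 1.0]], [[1.0, 0.0], [0.0, 1.0]]]
        )
        assert p_f(_map_from(v, normalized=True)) == pytest.approx(0.25)

    def test_unnormalized_input_rejected(self):
        m = _map_from(np.random.default_rng(0).random((2, 2, 3)))
        for measure in (p_a, p_g, p_f):
            with pytest.raises(ContractError):
                measure(m)

    def test_sample_estimator_flag(self):
        m = _all_ones_zero_map()
        assert p_a(m, ddof=1) == pytest.approx(0.25 * 8 / 7)

    def test_pa_upper_bound_k2(self):
        # with k=2 the normalized entries lie in [0,1]; variance is at most
        # 0.25, attained by the all-(1,0) extreme
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = normalize_histograms(_map_from(rng.random((3, 3, 2))))
            assert p_a(m) <= 0.25 + 1e-12


class TestFeatureVector:
    def test_45_values_and_names(self):
        feats = feature_vector(random_stack(0, k=4, h=32, w=32))
        assert feats.as_array().shape == (45,)
        assert feats.names() == feature_names()
        assert feats.names()[0] == "pa_02" and feats.names()[-1] == "pf_30"
        assert feats.P_a(22) == feats.as_array()[GRID_SIZES.index(22)]

    def test_scale_invariance(self):
        stack = random_stack(1, k=4, h=32, w=32)
        scaled = ResponseStack(1, stack.responses * 37.5)
        assert np.allclose(
            feature_vector(stack).as_array(), feature_vector(scaled).as_array()
        )

    def test_map_too_small(self):
        with pytest.raises(GridError, match="30"):
            feature_vector(random_stack(0, k=3, h=20, w=20))

    def test_spatially_constant_maps(self):
        # per-filter constants: P_f = 0 at every n, P_a independent of n
        consts = np.array([0.1, 0.5, 1.0, 2.0])
        stack = ResponseStack(1, np.tile(consts[:, None, None], (1, 32, 32)))
        feats = feature_vector(stack)
        assert np.allclose(feats.pf, 0.0)
        assert np.allclose(feats.pa, feats.pa[0])
        assert feats.pa[0] > 0


class TestSelfSimilarity:
    def test_identical_histograms_give_one(self):
        consts = np.array([1.0, 2.0, 3.0])
        stack = ResponseStack(1, np.tile(consts[:, None, None], (1, 16, 16)))
        assert self_similarity(stack).value == pytest.approx(1.0)

    def test_concentrated_ground_gives_minimal_overlap(self):
        # ground histogram dominated by a filter that is silent in 63 of the
        # 64 subregions: those contribute ~0 intersection.  The spike's own
        # subregion always matches the ground level (the global maximum lives
        # somewhere), so the infimum of the score on real response stacks is
        # 1/64, not 0.
        resp = np.zeros((2, 16, 16))
        resp[0, 0, 0] = 1e9
        resp[1] = 1.0
        score = self_similarity(ResponseStack(1, resp))
        assert score.value == pytest.approx(1.0 / 64.0, abs=1e-6)

    def test_bounded_and_small_map_rejected(self):
        assert 0.0 <= self_similarity(random_stack(3, h=16, w=16)).value <= 1.0
        with pytest.raises(GridError):
            self_similarity(random_stack(3, h=6, w=6))


class TestOracleEquivalence:
    def test_vectorized_matches_naive_on_battery(self):
        for seed in BATTERY_SEEDS:
            stack = random_stack(seed, k=5, h=6, w=6)
            for n in (1, 2, 3, 6):
                m = normalize_histograms(max_pool_map(stack, n))
                ref = naive_max_pool(stack.responses, n)
                ref /= ref.sum(axis=2, keepdims=True)
                assert np.allclose(m.values, ref, atol=1e-12)
                assert abs(p_a(m) - naive_pa(ref)) < 1e-10
                assert abs(p_g(m) - naive_pg(ref)) < 1e-10
                assert abs(p_f(m) - naive_pf(ref)) < 1e-10


@given(seed=st.integers(0, 2**31 - 1))
def test_normalization_conservation(seed):
    stack = random_stack(seed, k=6, h=9, w=7)
    m = normalize_histograms(max_pool_map(stack, 3))
    assert np.allclose(m.values.sum(axis=2), 1.0, atol=1e-9)
    assert m.values.min() >= 0.0


@given(seed=st.integers(0, 2**31 - 1))
def test_permutation_invariance(seed):
    rng = np.random.default_rng(seed)
    m = normalize_histograms(_map_from(rng.random((4, 4, 5))))
    perm_f = _map_from(m.values[:, :, rng.permutation(5)], normalized=True)
    # subregion permutation: shuffle the flattened grid cells
    cells = m.values.reshape(16, 5)[rng.permutation(16)].reshape(4, 4, 5)
    perm_s = _map_from(cells, normalized=True)
    for measure in (p_a, p_g, p_f):
        assert measure(perm_s) == pytest.approx(measure(m), abs=1e-12)
    assert p_a(perm_f) == pytest.approx(p_a(m), abs=1e-12)
    assert p_g(perm_f) == pytest.approx(p_g(m), abs=1e-12)
    assert p_f(perm_f) == pytest.approx(p_f(m), abs=1e-12)


@given(seed=st.integers(0, 2**31 - 1), scale=st.floats(1e-6, 1e6))
def test_response_scale_invariance(seed, scale):
    stack = random_stack(seed, k=4, h=12, w=12)
    scaled = ResponseStack(1, stack.responses * scale)
    for n in (2, 4):
        m1 = normalize_histograms(max_pool_map(stack, n))
        m2 = normalize_histograms(max_pool_map(scaled, n))
        assert p_a(m2) == pytest.approx(p_a(m1), rel=1e-9, abs=1e-12)
    assert self_similarity(scaled, grid=4).value == pytest.approx(
        self_similarity(stack, grid=4).value, rel=1e-9
    )


@given(seed=st.integers(0, 2**31 - 1))
def test_non_negativity(seed):
    stack = random_stack(seed, k=5, h=10, w=10)
    m = normalize_histograms(max_pool_map(stack, 5))
    assert p_a(m) >= 0 and p_g(m) >= 0 and p_f(m) >= 0
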