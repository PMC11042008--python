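"""SGA and SE blocks: frozen hand examples, scalar-loop oracles, invariants."""

import numpy as np
import pytest

from lesionseg import nn
from lesionseg.attention_blocks import (
    GroupedFeatureMap,
    SpatialGroupAttention,
    SqueezeExcitation,
    group_feature_map,
    se_excite,
    se_scale,
    se_squeeze,
    sga_forward,
    sga_group_mean,
    sga_normalize,
    sga_significance,
    ungroup_feature_map,
)
from lesionseg.nn import Tensor

from oracles import se_loop, sga_loop

SIGMOID_1 = 0.7310585786300049  # sigmoid(1), frozen by hand


# ---------------------------------------------------------------------------
# grouped view


def test_grouping_is_a_pure_view(rng):
    x = rng.normal(size=(2, 8, 3, 5)).astype(np.float32)
    g = group_feature_map(x, 4)
    assert g.values.shape == (2, 4, 2, 15)
    np.testing.assert_array_equal(ungroup_feature_map(g), x)


def test_grouping_rejects_indivisible_channels():
    with pytest.raises(ValueError, match="6.*4|4.*6"):
        group_feature_map(np.zeros((1, 6, 2, 2), dtype=np.float32), 4)


# ---------------------------------------------------------------------------
# SGA reference operations


def test_group_mean_hand_example():
    # two positions holding vectors (1,2) and (3,4) -> mean (2,3)
    vals = np.array([[1.0, 3.0], [2.0, 4.0]]).reshape(1, 1, 2, 2)
    g = GroupedFeatureMap(vals, 1, (1, 2))
    np.testing.assert_allclose(sga_group_mean(g), [[[2.0, 3.0]]])


def test_group_mean_constant_and_single_position(rng):
    const = GroupedFeatureMap(np.full((1, 2, 3, 7), 4.5), 2, (1, 7))
    np.testing.assert_allclose(sga_group_mean(const), 4.5)
    single = GroupedFeatureMap(rng.normal(size=(1, 2, 3, 1)), 2, (1, 1))
    np.testing.assert_allclose(sga_group_mean(single), single.values[..., 0])


def test_group_mean_rejects_empty_spatial_extent():
    g = GroupedFeatureMap(np.zeros((1, 1, 2, 0)), 1, (0, 0))
    with pytest.raises(ValueError, match="empty spatial"):
        sga_group_mean(g)


def test_significance_hand_example():
    # x_1=(1,2), x_2=(3,4), s=(2,3) -> dot products (8, 18)
    vals = np.array([[1.0, 3.0], [2.0, 4.0]]).reshape(1, 1, 2, 2)
    g = GroupedFeatureMap(vals, 1, (1, 2))
    coeff = sga_significance(g, np.array([2.0, 3.0]).reshape(1, 1, 2))
    np.testing.assert_allclose(coeff, [[[8.0, 18.0]]])


def test_significance_orthogonal_and_zero_context(rng):
    vals = np.array([[1.0], [0.0]]).reshape(1, 1, 2, 1)
    g = GroupedFeatureMap(vals, 1, (1, 1))
    np.testing.assert_allclose(sga_significance(g, np.array([[[0.0, 5.0]]])), 0.0)
    g2 = GroupedFeatureMap(rng.normal(size=(2, 3, 4, 6)), 3, (2, 3))
    np.testing.assert_allclose(sga_significance(g2, np.zeros((2, 3, 4))), 0.0)


def test_significance_rejects_mismatched_context(rng):
    g = GroupedFeatureMap(rng.normal(size=(1, 2, 3, 4)), 2, (2, 2))
    with pytest.raises(ValueError, match="does not match"):
        sga_significance(g, np.zeros((1, 3, 3)))


def test_normalize_hand_example_and_degenerate_cases():
    out = sga_normalize(np.array([[[8.0, 18.0]]]))  # mean 13, population std 5
    np.testing.assert_allclose(out, [[[-1.0, 1.0]]], atol=1e-4)
    np.testing.assert_array_equal(sga_normalize(np.full((2, 3, 5), 7.0)), 0.0)
    already = np.array([[[-1.0, 0.0, 1.0]]]) * np.sqrt(1.5)
    np.testing.assert_allclose(sga_normalize(already), already, atol=1e-4)


def test_normalize_statistics_property(rng):
    coeff = rng.normal(size=(3, 4, 25)) * 10 + 3
    out = sga_normalize(coeff)
    np.testing.assert_allclose(out.mean(-1), 0.0, atol=1e-4)
    np.testing.assert_allclose(out.std(-1), 1.0, atol=1e-4)


# ---------------------------------------------------------------------------
# SGA forward


def test_sga_forward_constant_input_gates_at_half(rng):
    x = np.full((2, 8, 4, 4), 1.7, dtype=np.float32)
    np.testing.assert_allclose(sga_forward(x, groups=4), 0.5 * x, atol=1e-6)
    block = SpatialGroupAttention(groups=4)
    np.testing.assert_allclose(block(Tensor(x)).data, 0.5 * x, atol=1e-6)


@pytest.mark.parametrize("groups", [1, 2, 4, 8])
def test_sga_forward_matches_scalar_loop_oracle(groups):
    rng = np.random.default_rng(groups)
    for trial in range(6):  # 6 trials x 4 group counts = 24 seeded inputs
        x = rng.normal(size=(2, 8, 4, 4)).astype(np.float32)
        gamma = rng.normal(size=groups).astype(np.float32)
        beta = rng.normal(size=groups).astype(np.float32)
        ref = sga_loop(x, groups, gamma=gamma, beta=beta)
        got = sga_forward(x, groups, gamma=gamma, beta=beta)
        assert np.abs(got - ref).max() < 1e-5
        block = SpatialGroupAttention(groups)
        block.gamma.data, block.beta.data = gamma, beta
        assert np.abs(block(Tensor(x)).data - ref).max() < 1e-5


def test_sga_forward_shape_and_gate_range(rng):
    x = rng.normal(size=(3, 16, 5, 6)).astype(np.float32)
    out = sga_forward(x, groups=8)
    assert out.shape == x.shape
    gate = np.where(x != 0, out / x, 0.5)
    assert ((gate > 0) & (gate < 1))[x != 0].all()


def test_sga_forward_large_beta_recovers_input(rng):
    # gamma -> 0, beta large: gate -> 1, output -> input
    x = rng.normal(size=(1, 8, 4, 4)).astype(np.float32)
    out = sga_forward(x, groups=2, gamma=np.zeros(2), beta=np.full(2, 20.0))
    np.testing.assert_allclose(out, x, rtol=1e-4, atol=1e-6)


def test_sga_forward_rejects_bad_group_count(rng):
    x = rng.normal(size=(1, 6, 4, 4)).astype(np.float32)
    with pytest.raises(ValueError, match="6.*4|4.*6"):
        sga_forward(x, groups=4)
    with pytest.raises(ValueError, match="6"):
        SpatialGroupAttention(groups=4)(Tensor(x))


# ---------------------------------------------------------------------------
# SE operations


def test_se_squeeze_hand_examples(rng):
    u = np.full((2, 3, 4, 5), 2.0)
    u[0, 1] = -1.0
    z = se_squeeze(u)
    assert z.shape == (2, 3)
    np.testing.assert_allclose(z[0], [2.0, -1.0, 2.0])
    u2 = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 2, 2)
    np.testing.assert_allclose(se_squeeze(u2), [[2.5]])


def test_se_excite_zero_weights_give_half_gates():
    z = np.array([[3.0, -2.0]])
    gates = se_excite(z, np.zeros((2, 2)), np.zeros((2, 2)))
    np.testing.assert_allclose(gates, 0.5)


def test_se_excite_hand_composition():
    # W1 = I, W2 = [[1,1],[1,-1]], z=(1,-1): hidden=relu(1,-1)=(1,0),
    # logits=(1,1) -> both gates sigmoid(1)
    w1 = np.eye(2)
    w2 = np.array([[1.0, 1.0], [1.0, -1.0]])
    gates = se_excite(np.array([[1.0, -1.0]]), w1, w2)
    np.testing.assert_allclose(gates, SIGMOID_1, rtol=1e-12)


def test_se_excite_gates_strictly_inside_unit_interval(rng):
    # moderate logits: the logistic range property, short of float saturation
    z = rng.normal(size=(4, 8))
    gates = se_excite(z, rng.normal(size=(2, 8)) * 0.5, rng.normal(size=(8, 2)) * 0.5)
    assert (gates > 0).all() and (gates < 1).all()


def test_se_excite_rejects_dimension_mismatch(rng):
    with pytest.raises(ValueError, match="W1"):
        se_excite(np.zeros((1, 4)), np.zeros((2, 3)), np.zeros((4, 2)))
    with pytest.raises(ValueError, match="W2"):
        se_excite(np.zeros((1, 4)), np.zeros((2, 4)), np.zeros((3, 2)))


def test_se_scale_identity_annihilation_and_loop(rng):
    u = rng.normal(size=(2, 2, 3, 3))
    np.testing.assert_array_equal(se_scale(u, np.ones((2, 2))), u)
    np.testing.assert_array_equal(se_scale(u, np.zeros((2, 2))), 0.0)
    s = np.array([[0.5, 0.25], [0.5, 0.25]])
    out = se_scale(u, s)
    for b in range(2):
        for c in range(2):
            for i in range(3):
                for j in range(3):
                    assert out[b, c, i, j] == u[b, c, i, j] * s[b, c]
    with pytest.raises(ValueError, match="gate length"):
        se_scale(u, np.ones((2, 3)))


def test_se_composition_matches_scalar_loop_oracle():
    rng = np.random.default_rng(99)
    for trial in range(20):
        u = rng.normal(size=(2, 4, 3, 5))
        w1 = rng.normal(size=(2, 4))
        w2 = rng.normal(size=(4, 2))
        ref = se_loop(u, w1, w2)
        got = se_scale(u, se_excite(se_squeeze(u), w1, w2))
        assert np.abs(got - ref).max() < 1e-5


def test_se_module_matches_reference_and_rejects_bad_ratio(rng):
    nn.seed_all(3)
    block = SqueezeExcitation(8, reduction=4)
    u = rng.normal(size=(2, 8, 4, 4)).astype(np.float32)
    ref = se_scale(u, se_excite(se_squeeze(u), block.fc1.weight.data, block.fc2.weight.data))
    np.testing.assert_allclose(block(Tensor(u)).data, ref, atol=1e-5)
    with pytest.raises(ValueError, match="divisible"):
        SqueezeExcitation(6, reduction=4)


def test_blocks_are_deterministic_and_shape_preserving(rng):
    x = rng.normal(size=(2, 16, 6, 6)).astype(np.float32)
    nn.seed_all(5)
    sga, se = SpatialGroupAttention(8), SqueezeExcitation(16, 4)
    a1, a2 = sga(Tensor(x)).data, sga(Tensor(x)).data
    b1, b2 = se(Tensor(x)).data, se(Tensor(x)).data
    np.testing.assert_array_equal(a1, a2)
    np.testing.assert_array_equal(b1, b2)
    assert a1.shape == x.shape and b1.shape == x.shape
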