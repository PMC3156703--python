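import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spermnet.dynamics import (
    KnockoutSpec,
    NoCycleFound,
    StateSpaceTooLarge,
    apply_knockout,
    enumerate_attractors,
    evaluate_node,
    simulate,
    step,
    step_indexed,
    successors,
)
from spermnet.fixtures import brute_force_landscape, make_cycle_network, make_identity_network
from spermnet.criticality import RandomNetworkParams, generate_random_network
from spermnet.model import NetworkModel, NodeSpec, TruthTable


def two_node_mutual_copy():
    nodes = [
        NodeSpec(id=0, name="a", arity=2, level_labels=("off", "on"), regulators=(1,)),
        NodeSpec(id=1, name="b", arity=2, level_labels=("off", "on"), regulators=(0,)),
    ]
    tabs = [
        TruthTable(node_id=i, regulator_arities=(2,), outputs=np.array([0, 1], dtype=np.int8))
        for i in range(2)
    ]
    return NetworkModel(nodes, tabs, name="mutual-copy")


def test_step_mutual_copy_swaps_levels():
    m = two_node_mutual_copy()
    assert np.array_equal(step(m, [0, 1]), [1, 0])
    assert np.array_equal(step(m, [1, 0]), [0, 1])


def test_step_is_deterministic_and_pure(speract_model):
    rng = np.random.default_rng(1)
    s = np.array([rng.integers(0, a) for a in speract_model.arities], dtype=np.int8)
    before = s.copy()
    out1 = step(speract_model, s)
    out2 = step(speract_model, s)
    assert np.array_equal(out1, out2)
    assert np.array_equal(s, before)  # input unmodified


def test_evaluate_node_matches_step(speract_model):
    rng = np.random.default_rng(2)
    for _ in range(20):
        s = np.array([rng.integers(0, a) for a in speract_model.arities], dtype=np.int8)
        nxt = step(speract_model, s)
        for i in range(speract_model.n_nodes):
            assert evaluate_node(speract_model, i, s) == nxt[i]
    with pytest.raises(KeyError):
        evaluate_node(speract_model, 99, s)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=3**2 * 2**3 - 1))
def test_step_indexed_equals_decode_step_encode(idx):
    from spermnet.fixtures import make_ternary_toggle

    m = make_ternary_toggle().model
    idx = idx % m.total_states
    assert step_indexed(m, idx) == m.encode(step(m, m.decode(idx)))


def test_bulk_successors_match_scalar_path(toy_fixtures):
    for fx in toy_fixtures:
        m = fx.model
        idx = np.arange(m.total_states)
        bulk = successors(m, idx)
        scalar = np.array([step_indexed(m, int(i)) for i in idx])
        assert np.array_equal(bulk, scalar)


def test_simulate_trajectory_contract(toy_fixtures):
    for fx in toy_fixtures:
        m = fx.model
        for idx in range(m.total_states):
            t = simulate(m, m.decode(idx))
            # transient states do not repeat
            codes = [m.encode(s) for s in t.states]
            assert len(set(codes)) == len(codes)
            # cycle closure: step maps each attractor state to the next
            for k in range(t.period):
                nxt = step(m, t.attractor[k])
                assert np.array_equal(nxt, t.attractor[(k + 1) % t.period])
            if t.transient_length:
                assert np.array_equal(
                    step(m, t.states[t.transient_length - 1]), t.attractor[0]
                )


def test_simulate_on_point_attractor_has_zero_transient():
    m = make_identity_network(4).model
    t = simulate(m, [1, 0, 1, 1])
    assert t.transient_length == 0 and t.period == 1


def test_simulate_raises_without_cycle_budget():
    m = make_cycle_network(5).model
    with pytest.raises(ValueError):
        simulate(m, m.decode(0), max_steps=0)
    with pytest.raises(NoCycleFound):
        simulate(m, m.decode(1), max_steps=1)


def test_enumerate_matches_naive_oracle_on_fixtures_and_rbns(toy_fixtures):
    """Oracle equivalence: vectorized enumeration == per-state brute force."""
    models = [fx.model for fx in toy_fixtures]
    for seed in (0, 1, 2):
        models.append(
            generate_random_network(RandomNetworkParams(n_nodes=9, k_inputs=2, bias=0.5, seed=seed))
        )
    for m in models:
        land = enumerate_attractors(m)
        oracle = brute_force_landscape(m)
        assert land.n_attractors == oracle["n_attractors"]
        assert sorted(land.periods) == sorted(oracle["periods"])
        assert sorted(land.basin_sizes.tolist()) == sorted(oracle["basin_sizes"])
        # exact cycle identity, not just counts
        got = sorted(tuple(m.encode_many(a).tolist()) for a in land.attractors)
        want = sorted(tuple(c) for c in oracle["cycles"])
        assert got == want


def test_landscape_partition_identity(toy_fixtures):
    for fx in toy_fixtures:
        land = enumerate_attractors(fx.model)
        assert int(land.basin_sizes.sum()) == land.total_states == fx.model.total_states
        all_states = [tuple(s) for a in land.attractors for s in a]
        assert len(all_states) == len(set(all_states))  # attractors disjoint


def test_enumerate_restrict_counts_only_matching_states():
    m = make_identity_network(3).model
    land = enumerate_attractors(m, restrict=lambda mat: mat[:, 0] == 1)
    assert land.total_states == 4
    assert land.n_attractors == 4
    assert all(a[0, 0] == 1 for a in land.attractors)


def test_enumerate_refuses_oversized_state_space(speract_model):
    with pytest.raises(StateSpaceTooLarge):
        enumerate_attractors(speract_model, max_states=1000)


def test_canonical_rotation_minimal_state_first():
    m = make_cycle_network(3).model
    land = enumerate_attractors(m)
    for a in land.attractors:
        codes = m.encode_many(a)
        assert codes[0] == codes.min()


def test_apply_knockout_clamps_and_preserves_original():
    m = make_cycle_network(3).model
    ko = apply_knockout(m, KnockoutSpec(clamps={1: 0}))
    # original untouched
    assert m.tables[1].outputs.tolist() == [0, 1]
    assert set(ko.tables[1].outputs.tolist()) == {0}
    # clamp invariance: node holds its level from step 1 in every trajectory
    for idx in range(m.total_states):
        t = simulate(ko, m.decode(idx))
        assert all(s[1] == 0 for s in t.states[1:])
        assert all(s[1] == 0 for s in t.attractor)
    with pytest.raises(ValueError):
        apply_knockout(m, KnockoutSpec(clamps={1: 5}))
    with pytest.raises(KeyError):
        apply_knockout(m, KnockoutSpec(clamps={9: 0}))
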