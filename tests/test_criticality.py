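import numpy as np
import pytest

from spermnet.criticality import (
    RandomNetworkParams,
    classify_regime,
    derrida_map,
    exact_sensitivity,
    generate_random_network,
    perturb,
)
from spermnet.fixtures import make_identity_network


def constant_network(n=5, seed=0):
    return generate_random_network(RandomNetworkParams(n_nodes=n, k_inputs=2, bias=0.0, seed=seed))


def test_perturb_changes_exactly_m_nodes(speract_model):
    rng = np.random.default_rng(0)
    base = np.zeros(speract_model.n_nodes, dtype=np.int8)
    for m in (1, 2, 5, speract_model.n_nodes):
        for _ in range(20):
            p = perturb(speract_model, base, m, rng)
            assert int((p != base).sum()) == m
            speract_model.validate_state(p)  # levels stay admissible
    with pytest.raises(ValueError):
        perturb(speract_model, base, 0, rng)
    with pytest.raises(ValueError):
        perturb(speract_model, base, speract_model.n_nodes + 1, rng)


def test_derrida_identity_network_lies_on_diagonal():
    m = make_identity_network(10).model
    curve = derrida_map(m, d_values=[1, 2, 5, 10], n_samples=200, seed=3)
    assert np.allclose(curve.d_out, curve.d_in)
    assert curve.slope_at_origin == pytest.approx(1.0)
    assert classify_regime(curve, tolerance=0.05) == "critical"


def test_derrida_constant_network_collapses_to_zero():
    m = constant_network()
    curve = derrida_map(m, d_values=[1, 2, 5], n_samples=200, seed=4)
    assert np.all(curve.d_out == 0)
    assert curve.slope_at_origin == 0.0
    assert classify_regime(curve) == "ordered"
    assert exact_sensitivity(m) == 0.0


def test_derrida_map_reproducible_and_increasing_d_in(speract_model):
    c1 = derrida_map(speract_model, [1, 4, 8], n_samples=500, seed=11)
    c2 = derrida_map(speract_model, [1, 4, 8], n_samples=500, seed=11)
    assert np.array_equal(c1.d_out, c2.d_out)
    assert np.all(np.diff(c1.d_in) > 0)
    assert np.all((0 <= c1.d_out) & (c1.d_out <= 1))


def test_exact_sensitivity_identity_is_one():
    assert exact_sensitivity(make_identity_network(6).model) == pytest.approx(1.0)


def test_exact_sensitivity_sampled_agrees_with_closed_form():
    m = generate_random_network(RandomNetworkParams(n_nodes=10, k_inputs=2, bias=0.5, seed=9))
    exact = exact_sensitivity(m)
    sampled = exact_sensitivity(m, n_states=4000, seed=1)
    assert sampled == pytest.approx(exact, abs=0.08)


def test_monte_carlo_slope_converges_to_exact_sensitivity():
    m = generate_random_network(RandomNetworkParams(n_nodes=12, k_inputs=2, bias=0.5, seed=5))
    exact = exact_sensitivity(m)
    errs = []
    for n in (100, 1000, 10000):
        c = derrida_map(m, [1], n_samples=n, seed=21)
        errs.append(abs(c.slope_at_origin - exact))
    assert errs[-1] < 0.1
    assert errs[-1] <= errs[0] + 0.05  # error shrinks (allowing MC noise)


def test_rbn_ensemble_sensitivity_matches_annealed_approximation():
    """Mean sensitivity of K-input bias-p random nets is 2p(1-p)K within 3 SE."""
    for k in (1, 2, 4):
        vals = [
            exact_sensitivity(
                generate_random_network(
                    RandomNetworkParams(n_nodes=50, k_inputs=k, bias=0.5, seed=100 * k + i)
                )
            )
            for i in range(60)
        ]
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        expected = 2 * 0.5 * 0.5 * k  # K/2
        assert abs(mean - expected) < 3 * max(se, 1e-9), (k, mean, se)


def test_generate_random_network_reproducible_and_valid():
    p = RandomNetworkParams(n_nodes=20, k_inputs=3, bias=0.3, seed=42)
    m1, m2 = generate_random_network(p), generate_random_network(p)
    for t1, t2 in zip(m1.tables, m2.tables):
        assert np.array_equal(t1.outputs, t2.outputs)
    assert all(len(set(n.regulators)) == 3 for n in m1.nodes)
    with pytest.raises(ValueError):
        RandomNetworkParams(n_nodes=3, k_inputs=4, bias=0.5, seed=0)


def test_classify_regime_thresholds():
    m = make_identity_network(4).model
    curve = derrida_map(m, [1], n_samples=50, seed=0)
    # identity slope is exactly 1
    assert classify_regime(curve, tolerance=0.05) == "critical"
    chaotic = generate_random_network(RandomNetworkParams(50, 4, 0.5, seed=2))
    c2 = derrida_map(chaotic, [1], n_samples=4000, seed=3)
    assert classify_regime(c2, tolerance=0.2) == "chaotic"
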