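import numpy as np
import pytest

from spermnet.dynamics import apply_knockout, simulate, step
from spermnet.phenotype import summarize_phenotype
from spermnet.speract import (
    NODE_ORDER,
    build_speract_model,
    preset_knockouts,
    wildtype_basal_init,
)


def test_structural_census(speract_model):
    """22 nodes, 18 binary + 4 ternary, full mixed-radix state count."""
    m = speract_model
    assert m.n_nodes == 22
    arity_counts = {2: 0, 3: 0}
    for n in m.nodes:
        arity_counts[n.arity] += 1
    assert arity_counts == {2: 18, 3: 4}
    ternary = {n.name for n in m.nodes if n.arity == 3}
    assert ternary == {"V", "HVA", "LVA", "Ca"}
    assert m.total_states == 2**18 * 3**4


def test_ca_table_has_432_rows_and_7_regulators(speract_model):
    ca = speract_model.node_id("Ca")
    node = speract_model.nodes[ca]
    assert len(node.regulators) == 7
    ternary_regs = sum(1 for r in node.regulators if speract_model.nodes[r].arity == 3)
    assert ternary_regs == 3
    assert speract_model.tables[ca].n_rows == 432


def test_camp_table_pde_dominant_inhibition(speract_model):
    """If PDE is on at time t, cAMP is off at t+1 regardless of activators."""
    camp = speract_model.node_id("cAMP")
    node = speract_model.nodes[camp]
    tab = speract_model.tables[camp]
    names = [speract_model.nodes[r].name for r in node.regulators]
    pde_pos = names.index("PDE")
    for row, out in zip(tab.rows(), tab.outputs):
        if row[pde_pos] == 1:
            assert out == 0
    # self-activation: cAMP on sustains itself when PDE is off
    camp_pos = names.index("cAMP")
    for row, out in zip(tab.rows(), tab.outputs):
        if row[pde_pos] == 0 and row[camp_pos] == 1:
            assert out == 1


def test_node_roster_matches_declared_order(speract_model):
    assert tuple(speract_model.node_names) == NODE_ORDER


def test_basal_init_shapes(speract_model):
    on = wildtype_basal_init(speract_model, 1)
    assert int((on != 0).sum()) == 1
    assert on[speract_model.node_id("speract")] == 1
    off = wildtype_basal_init(speract_model, 0)
    assert not off.any()
    with pytest.raises(ValueError):
        wildtype_basal_init(speract_model, 2)


def test_speract_sector_closure(speract_model):
    """No trajectory ever changes the speract level (constant-input node)."""
    rng = np.random.default_rng(3)
    sp = speract_model.node_id("speract")
    for _ in range(40):
        s = np.array([rng.integers(0, a) for a in speract_model.arities], dtype=np.int8)
        lev = s[sp]
        for _ in range(30):
            s = step(speract_model, s)
            assert s[sp] == lev


def test_speract_off_reaches_basal_point_attractor(speract_model):
    """Without speract every sampled state reaches a fixed point quickly."""
    rng = np.random.default_rng(4)
    for _ in range(60):
        s = np.array([rng.integers(0, a) for a in speract_model.arities], dtype=np.int8)
        s[0] = 0
        t = simulate(speract_model, s)
        assert t.period == 1
        assert t.transient_length < 40


def test_preset_knockouts_are_clamp_to_zero(speract_model):
    presets = preset_knockouts(speract_model)
    assert set(presets) == {"dK", "LVA", "PDE", "CaCC", "CaKC", "HVA"}
    for name, spec in presets.items():
        assert spec.clamps == {speract_model.node_id(name): 0}


def test_wildtype_attractor_period4_supratonic_quarter(speract_model):
    traj = simulate(speract_model, wildtype_basal_init(speract_model))
    ph = summarize_phenotype(traj, speract_model.node_id("Ca"))
    assert ph.period == 4
    assert ph.supratonic_count == 1
    assert float(ph.supratonic_fraction) == 0.25
    assert ph.oscillating


def test_random_speract_on_inits_reach_period_4_or_8(speract_model):
    rng = np.random.default_rng(11)
    for _ in range(200):
        s = np.array([rng.integers(0, a) for a in speract_model.arities], dtype=np.int8)
        s[0] = 1
        t = simulate(speract_model, s)
        assert t.period in (4, 8)
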