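"""Small code-generated test networks with analytically known dynamics.

Each fixture bundles a model with an ``expected`` block holding ground truth
(attractor periods, basin sizes, sensitivity) that is either closed-form or
produced by exhaustive brute force at construction time, so the truth can
never drift from the generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import NetworkModel, NodeSpec, TruthTable

__all__ = [
    "FixtureNetwork",
    "make_identity_network",
    "make_cycle_network",
    "make_ternary_toggle",
    "brute_force_landscape",
]


@dataclass(frozen=True)
class FixtureNetwork:
    model: NetworkModel
    expected: dict


def _binary_node(i: int, name: str, regulators: tuple[int, ...]) -> NodeSpec:
    return NodeSpec(id=i, name=name, arity=2, level_labels=("off", "on"), regulators=regulators)


def make_identity_network(n: int) -> FixtureNetwork:
    """n binary nodes, each copying itself: 2**n point attractors, basins of 1."""
    if n < 1:
        raise ValueError("n >= 1")
    nodes = [_binary_node(i, f"x{i}", (i,)) for i in range(n)]
    tables = [
        TruthTable(node_id=i, regulator_arities=(2,), outputs=np.array([0, 1], dtype=np.int8))
        for i in range(n)
    ]
    model = NetworkModel(nodes, tables, name=f"identity-{n}")
    return FixtureNetwork(
        model=model,
        expected={
            "n_attractors": 2**n,
            "periods": [1] * 2**n,
            "basin_sizes": [1] * 2**n,
            "sensitivity": 1.0,
        },
    )


def make_cycle_network(n: int) -> FixtureNetwork:
    """Directed copy-ring: node i copies node i-1 (mod n).

    The dynamics rotates bit-necklaces; expected attractors are computed by
    brute force over all 2**n states at build time.
    """
    if n < 2:
        raise ValueError("n >= 2")
    nodes = [_binary_node(i, f"x{i}", ((i - 1) % n,)) for i in range(n)]
    tables = [
        TruthTable(node_id=i, regulator_arities=(2,), outputs=np.array([0, 1], dtype=np.int8))
        for i in range(n)
    ]
    model = NetworkModel(nodes, tables, name=f"ring-{n}")
    expected = brute_force_landscape(model)
    expected["sensitivity"] = 1.0  # each node is a bijection of its single input
    return FixtureNetwork(model=model, expected=expected)


def make_ternary_toggle() -> FixtureNetwork:
    """One binary clock (inverts itself) driving a ternary counter.

    The ternary node advances one level (mod 3) whenever the clock is on and
    holds otherwise; exercises mixed-radix encode/decode and ternary
    perturbations.  Ground truth comes from brute force over the 6 states.
    """
    clock = _binary_node(0, "clock", (0,))
    counter = NodeSpec(
        id=1, name="counter", arity=3, level_labels=("lo", "mid", "hi"), regulators=(0, 1)
    )
    t_clock = TruthTable(node_id=0, regulator_arities=(2,), outputs=np.array([1, 0], dtype=np.int8))
    # rows in (clock, counter) order
    outs = np.array(
        [
            0, 1, 2,  # clock 0: hold
            1, 2, 0,  # clock 1: advance
        ],
        dtype=np.int8,
    )
    t_counter = TruthTable(node_id=1, regulator_arities=(2, 3), outputs=outs)
    model = NetworkModel([clock, counter], [t_clock, t_counter], name="ternary-toggle")
    expected = brute_force_landscape(model)
    return FixtureNetwork(model=model, expected=expected)


def brute_force_landscape(model: NetworkModel) -> dict:
    """Naive per-state simulate-until-repeat oracle (small models only).

    Independent of the vectorized enumeration path: walks each state with the
    scalar ``step`` until a repeat, canonicalizes the cycle by minimal encoded
    state, and tallies basins.
    """
    from .dynamics import step

    n = model.total_states
    if n > 1 << 14:
        raise ValueError("brute force oracle is for small models")
    cycles: dict[tuple[int, ...], int] = {}
    basin: dict[int, int] = {}
    for idx in range(n):
        s = model.decode(idx)
        seen: dict[int, int] = {}
        code = model.encode(s)
        while code not in seen:
            seen[code] = len(seen)
            s = step(model, s)
            code = model.encode(s)
        # walk out the cycle
        cyc = [code]
        t = step(model, model.decode(code))
        tcode = model.encode(t)
        while tcode != code:
            cyc.append(tcode)
            t = step(model, t)
            tcode = model.encode(t)
        k = int(np.argmin(cyc))
        key = tuple(cyc[k:] + cyc[:k])
        lab = cycles.setdefault(key, len(cycles))
        basin[lab] = basin.get(lab, 0) + 1
    keys = sorted(cycles, key=lambda c: c[0])
    periods = [len(k) for k in keys]
    sizes = [basin[cycles[k]] for k in keys]
    return {
        "n_attractors": len(keys),
        "periods": periods,
        "basin_sizes": sizes,
        "cycles": [list(k) for k in keys],
    }
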