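"""Derrida-map analysis and dynamical-regime classification.

The Derrida map relates the size of a perturbation avalanche at two
consecutive time steps: draw a base state, flip ``m`` nodes to different
admissible levels, advance both states one synchronous step, and record the
number of nodes at which the images differ.  The slope of the map at the
origin (expected number of differing nodes after one step, given a single
initially differing node) classifies the dynamics: ordered below 1, critical
at 1, chaotic above 1.

``exact_sensitivity`` is the deterministic cross-check of the Monte-Carlo
slope.  Under the uniform measure on the full state space the node levels
are independent, so the exact average over all states and all single-node
perturbations factorizes into per-truth-table row averages; the sampled mode
instead enumerates every single perturbation of each sampled base state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import step, successors
from .model import NetworkModel, NodeSpec, TruthTable

__all__ = [
    "DerridaCurve",
    "RandomNetworkParams",
    "perturb",
    "derrida_map",
    "exact_sensitivity",
    "generate_random_network",
    "classify_regime",
]


@dataclass(frozen=True)
class DerridaCurve:
    """One-step Derrida map: normalized separations before/after one update."""

    d_in: np.ndarray  # fractions m/N, strictly increasing
    d_out: np.ndarray  # mean normalized separations after one step
    stderr: np.ndarray  # standard error of each d_out
    n_samples: int
    seed: int
    slope_at_origin: float  # expected differing nodes after one step at m=1

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.d_in.tolist(), self.d_out.tolist()))


@dataclass(frozen=True)
class RandomNetworkParams:
    """Kauffman-style random Boolean network: N nodes, K inputs, bias p."""

    n_nodes: int
    k_inputs: int
    bias: float
    seed: int

    def __post_init__(self) -> None:
        if not 1 <= self.k_inputs <= self.n_nodes:
            raise ValueError("1 <= k_inputs <= n_nodes required")
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError("bias must be in [0, 1]")


def perturb(model: NetworkModel, state, m: int, rng: np.random.Generator) -> np.ndarray:
    """Flip exactly ``m`` distinct, uniformly chosen nodes to other levels.

    For a multi-level node the new level is uniform over the other admissible
    levels, so the node-difference count is exactly ``m``.
    """
    s = model.validate_state(state).astype(np.int8).copy()
    n = model.n_nodes
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}], got {m}")
    which = rng.choice(n, size=m, replace=False)
    for i in which:
        a = int(model.arities[i])
        shift = int(rng.integers(1, a))
        s[i] = (int(s[i]) + shift) % a
    return s


def _random_states(model: NetworkModel, k: int, rng: np.random.Generator) -> np.ndarray:
    """k uniform states as a (k, N) level matrix."""
    cols = [rng.integers(0, int(a), size=k) for a in model.arities]
    return np.stack(cols, axis=1).astype(np.int8)


def _perturb_many(
    model: NetworkModel, states: np.ndarray, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized perturb: flip m distinct nodes per row."""
    k, n = states.shape
    out = states.copy()
    # sample m distinct node columns per row via argpartition of random keys
    keys = rng.random((k, n))
    which = np.argpartition(keys, m - 1, axis=1)[:, :m]
    rows = np.repeat(np.arange(k), m)
    cols = which.ravel()
    a = model.arities[cols]
    shift = (rng.random(cols.size) * (a - 1)).astype(np.int64) + 1
    out[rows, cols] = ((states[rows, cols].astype(np.int64) + shift) % a).astype(np.int8)
    return out


def derrida_map(
    model: NetworkModel,
    d_values,
    n_samples: int,
    seed: int,
    restrict_node: int | None = None,
    restrict_level: int | None = None,
) -> DerridaCurve:
    """Monte-Carlo Derrida map of a model.

    Parameters
    ----------
    d_values : sequence of int
        Initial node-difference counts ``m`` (each in ``[1, N]``).
    n_samples : int
        Pairs of states per ``m``.
    restrict_node, restrict_level : optional
        When given, base states are sampled uniformly from the sector where
        that node sits at that level (e.g. the speract-on sector) instead of
        the full state space; the perturbation may still touch any node.
    """
    ms = sorted(set(int(m) for m in d_values))
    if not ms:
        raise ValueError("d_values must be non-empty")
    if n_samples < 1:
        raise ValueError("n_samples >= 1")
    n = model.n_nodes
    rng = np.random.default_rng(seed)
    d_in, d_out, se = [], [], []
    slope = np.nan
    for m in ms:
        if not 1 <= m <= n:
            raise ValueError(f"m={m} outside [1, {n}]")
        base = _random_states(model, n_samples, rng)
        if restrict_node is not None:
            base[:, restrict_node] = restrict_level
        pert = _perturb_many(model, base, m, rng)
        s1 = model.decode_many(successors(model, model.encode_many(base)))
        s2 = model.decode_many(successors(model, model.encode_many(pert)))
        diff = (s1 != s2).sum(axis=1)
        d_in.append(m / n)
        d_out.append(float(diff.mean()) / n)
        se.append(float(diff.std(ddof=1)) / np.sqrt(n_samples) / n if n_samples > 1 else np.nan)
        if m == 1:
            slope = float(diff.mean())  # raw node-count scale: d_out(1)/1
    return DerridaCurve(
        d_in=np.array(d_in),
        d_out=np.array(d_out),
        stderr=np.array(se),
        n_samples=n_samples,
        seed=seed,
        slope_at_origin=slope,
    )


def exact_sensitivity(
    model: NetworkModel,
    n_states: int | str = "exhaustive",
    seed: int | None = None,
    max_rows: int = 1 << 24,
) -> float:
    """Average network sensitivity: the deterministic m=1 Derrida slope.

    ``n_states="exhaustive"`` computes the exact average over *all* base
    states and all single-node perturbations (each perturbed node chosen
    uniformly, its new level uniform over the other levels).  Because the
    uniform measure factorizes over nodes, this equals a per-truth-table row
    average and costs only the table sizes, independent of the state-space
    size.  An integer ``n_states`` instead samples that many uniform base
    states and enumerates every single perturbation of each.
    """
    if n_states == "exhaustive":
        total_rows = sum(t.n_rows * max(1, len(model.nodes[i].regulators))
                         for i, t in enumerate(model.tables))
        if total_rows > max_rows:
            raise MemoryError("table enumeration above budget; use sampled mode")
        per_perturbed = np.zeros(model.n_nodes)  # E[#changed | perturb node j]
        for i, node in enumerate(model.nodes):
            tab = model.tables[i]
            if not node.regulators:
                continue
            rows = tab.rows()  # (R, k)
            outs = tab.outputs
            for pos, j in enumerate(node.regulators):
                a = int(model.arities[j])
                # probability output changes when regulator j is redrawn
                # uniformly among its other levels
                changed = 0.0
                for shift in range(1, a):
                    alt = rows.copy()
                    alt[:, pos] = (alt[:, pos] + shift) % a
                    alt_rows = np.ravel_multi_index(
                        tuple(alt[:, c] for c in range(alt.shape[1])), tab.regulator_arities
                    )
                    changed += float(np.mean(outs[alt_rows] != outs))
                per_perturbed[j] += changed / (a - 1)
        return float(per_perturbed.mean())

    if seed is None:
        raise ValueError("sampled mode requires a seed")
    rng = np.random.default_rng(seed)
    k = int(n_states)
    base = _random_states(model, k, rng)
    img_base = model.decode_many(successors(model, model.encode_many(base)))
    total = 0.0
    for j in range(model.n_nodes):
        a = int(model.arities[j])
        for shift in range(1, a):
            pert = base.copy()
            pert[:, j] = ((pert[:, j].astype(np.int64) + shift) % a).astype(np.int8)
            img = model.decode_many(successors(model, model.encode_many(pert)))
            diff = (img != img_base).sum(axis=1)
            # uniform choice of perturbed node, uniform alternative level
            total += diff.sum() / (a - 1)
    return float(total / (k * model.n_nodes))


def generate_random_network(params: RandomNetworkParams) -> NetworkModel:
    """Random Boolean network: K distinct regulators per node, Bernoulli(p) outputs."""
    rng = np.random.default_rng(params.seed)
    n, k = params.n_nodes, params.k_inputs
    nodes, tables = [], []
    for i in range(n):
        regs = tuple(int(r) for r in rng.choice(n, size=k, replace=False))
        nodes.append(
            NodeSpec(id=i, name=f"x{i}", arity=2, level_labels=("off", "on"), regulators=regs)
        )
        outs = (rng.random(2**k) < params.bias).astype(np.int8)
        tables.append(TruthTable(node_id=i, regulator_arities=(2,) * k, outputs=outs))
    return NetworkModel(
        nodes,
        tables,
        name=f"rbn-N{n}-K{k}-p{params.bias}",
        metadata={"seed": str(params.seed)},
    )


def classify_regime(curve: DerridaCurve, tolerance: float = 0.05) -> str:
    """Ordered / critical / chaotic from the slope at the origin."""
    s = curve.slope_at_origin
    if np.isnan(s):
        raise ValueError("curve has no m=1 point; slope at origin undefined")
    if s < 1.0 - tolerance:
        return "ordered"
    if s > 1.0 + tolerance:
        return "chaotic"
    return "critical"
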