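"""Synchronous dynamics: evaluation, simulation, exhaustive attractor search.

The update is deterministic and synchronous: every node reads the *current*
global state and all nodes switch to their table outputs simultaneously.
The state-transition system is therefore a functional graph (each state has
exactly one successor), so every trajectory consists of a transient followed
by a periodic cycle (attractor), and the state space partitions exactly into
basins of attraction.

Exhaustive enumeration works on the mixed-radix state index: the successor
of every index is computed blockwise and the map is collapsed by pointer
doubling, after which each state's image lies on its attractor cycle and
basins are exact counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import NetworkModel, NodeSpec, TruthTable

__all__ = [
    "Trajectory",
    "AttractorLandscape",
    "KnockoutSpec",
    "NoCycleFound",
    "StateSpaceTooLarge",
    "evaluate_node",
    "step",
    "step_indexed",
    "successors",
    "simulate",
    "enumerate_attractors",
    "apply_knockout",
]

#: default refusal ceiling for exhaustive enumeration (number of states)
DEFAULT_MAX_STATES = 2**28


class NoCycleFound(RuntimeError):
    """Raised when simulate() exhausts max_steps before revisiting a state."""


class StateSpaceTooLarge(RuntimeError):
    """Raised instead of silently sampling when the state space exceeds the budget."""


@dataclass(frozen=True)
class Trajectory:
    """One run: transient prefix plus the detected attractor cycle.

    ``states`` holds the visited states from the initial condition up to (and
    including) the step just before the first revisited state; the first
    ``transient_length`` rows are the transient, the rest are one full period
    of the attractor in visit order.
    """

    states: np.ndarray  # (transient_length + period, N)
    transient_length: int
    attractor: np.ndarray  # (period, N), cycle in visit order
    period: int

    @property
    def n_steps(self) -> int:
        return self.states.shape[0]

    def levels_of(self, node_id: int) -> np.ndarray:
        """Time course of one node over the recorded states."""
        return self.states[:, node_id]


@dataclass(frozen=True)
class AttractorLandscape:
    """All attractors of a model with canonical cycles and exact basin sizes.

    Each attractor cycle is rotated so that its minimal encoded state comes
    first (canonical form), making attractor identity independent of the
    entry point.  ``basin_sizes[k]`` counts the states (within the enumerated
    set) whose trajectory ends on attractor ``k``.
    """

    attractors: tuple[np.ndarray, ...]  # each (period, N)
    basin_sizes: np.ndarray  # (n_attractors,) int64
    total_states: int

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)

    @property
    def periods(self) -> list[int]:
        return [a.shape[0] for a in self.attractors]


@dataclass(frozen=True)
class KnockoutSpec:
    """Clamp a set of nodes to fixed levels (node deletion semantics)."""

    clamps: dict[int, int]


# -- single-state operations ---------------------------------------------------


def evaluate_node(model: NetworkModel, node_id: int, state) -> int:
    """Next level of one node given the current global state."""
    if not 0 <= node_id < model.n_nodes:
        raise KeyError(f"unknown node id {node_id}")
    s = model.validate_state(state)
    tab = model.tables[node_id]
    regs = model.nodes[node_id].regulators
    if not regs:
        return int(tab.outputs[0])
    row = tab.row_index(tuple(int(s[r]) for r in regs))
    return int(tab.outputs[row])


def step(model: NetworkModel, state) -> np.ndarray:
    """Synchronous update: all nodes switch simultaneously."""
    s = model.validate_state(state)
    out = np.empty(model.n_nodes, dtype=np.int8)
    for i in range(model.n_nodes):
        tab = model.tables[i]
        regs = model.nodes[i].regulators
        if not regs:
            out[i] = tab.outputs[0]
            continue
        row = tab.row_index(tuple(int(s[r]) for r in regs))
        out[i] = tab.outputs[row]
    return out


def step_indexed(model: NetworkModel, index: int) -> int:
    """Successor on the mixed-radix index: encode(step(decode(index)))."""
    return model.encode(step(model, model.decode(index)))


def successors(model: NetworkModel, indices: np.ndarray) -> np.ndarray:
    """Vectorized successor map over an array of state indices."""
    digits = model.decode_many(indices)  # (m, N)
    nxt = np.zeros(digits.shape[0], dtype=np.int64)
    for i in range(model.n_nodes):
        tab = model.tables[i]
        regs = model.nodes[i].regulators
        if regs:
            row = np.zeros(digits.shape[0], dtype=np.int64)
            stride = 1
            for r, a in zip(reversed(regs), reversed(tab.regulator_arities)):
                row += digits[:, r].astype(np.int64) * stride
                stride *= a
            lev = tab.outputs[row].astype(np.int64)
        else:
            lev = np.full(digits.shape[0], int(tab.outputs[0]), dtype=np.int64)
        nxt += lev * int(model._strides[i])
    return nxt


# -- simulation ----------------------------------------------------------------


def simulate(model: NetworkModel, initial, max_steps: int = 100_000) -> Trajectory:
    """Iterate from ``initial`` until a state repeats; split transient/cycle.

    Cycle detection is first-revisit of a stored state; with
    ``max_steps >= total_states`` a cycle is guaranteed.  Raises
    :class:`NoCycleFound` otherwise.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    s = model.validate_state(initial).astype(np.int8)
    seen: dict[int, int] = {}
    states: list[np.ndarray] = []
    code = model.encode(s)
    for t in range(max_steps + 1):
        if code in seen:
            first = seen[code]
            arr = np.array(states, dtype=np.int8)
            return Trajectory(
                states=arr,
                transient_length=first,
                attractor=arr[first:],
                period=len(states) - first,
            )
        seen[code] = t
        states.append(s.copy())
        s = step(model, s)
        code = model.encode(s)
    raise NoCycleFound(f"no cycle within {max_steps} steps")


# -- exhaustive enumeration ----------------------------------------------------


def _canonical_rotation(cycle_codes: list[int]) -> list[int]:
    k = int(np.argmin(cycle_codes))
    return cycle_codes[k:] + cycle_codes[:k]


def enumerate_attractors(
    model: NetworkModel,
    restrict=None,
    max_states: int = DEFAULT_MAX_STATES,
    block: int = 1 << 20,
) -> AttractorLandscape:
    """Exact attractor landscape over the full state space.

    Parameters
    ----------
    restrict : callable or None
        Optional predicate on decoded states (vectorized: receives an
        ``(m, N)`` level matrix, returns a boolean mask).  When given, only
        states satisfying the predicate are counted as initial conditions
        (trajectories still follow the full dynamics), and only attractors
        reached from them are reported.
    max_states : int
        Refusal ceiling; enumeration above it raises
        :class:`StateSpaceTooLarge` rather than silently sampling.
    """
    n = model.total_states
    if n > max_states:
        raise StateSpaceTooLarge(
            f"state space has {n} states, above the ceiling of {max_states}; "
            "raise max_states explicitly to proceed"
        )

    succ = np.empty(n, dtype=np.int64)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        succ[lo:hi] = successors(model, np.arange(lo, hi, dtype=np.int64))

    # Pointer doubling: after k squarings ptr == succ^(2^k).  Once 2^k exceeds
    # every transient length, ptr[s] lies on s's attractor cycle.  We square
    # until the image set stops shrinking, then verify cyclicity directly.
    ptr = succ.copy()
    prev_img_size = None
    for _ in range(64):
        ptr = ptr[ptr]
        img = np.unique(ptr)
        if prev_img_size is not None and img.size == prev_img_size:
            # candidate cycle states: every image state must return to itself
            on_cycle = _all_cyclic(succ, img)
            if on_cycle:
                break
        prev_img_size = img.size
    else:  # pragma: no cover - cannot happen: 2^64 exceeds any transient
        raise RuntimeError("pointer doubling failed to converge")

    # label each cycle found among image states
    label_of: dict[int, int] = {}
    attractor_cycles: list[list[int]] = []
    for s0 in img.tolist():
        if s0 in label_of:
            continue
        cyc = [s0]
        s = int(succ[s0])
        while s != s0:
            cyc.append(s)
            s = int(succ[s])
        lab = len(attractor_cycles)
        attractor_cycles.append(_canonical_rotation(cyc))
        for c in cyc:
            label_of[c] = lab

    labels_img = np.array([label_of[int(c)] for c in img], dtype=np.int64)
    # map every state's ptr (a cycle state) to its attractor label
    pos = np.searchsorted(img, ptr)
    state_labels = labels_img[pos]

    if restrict is not None:
        mask = np.empty(n, dtype=bool)
        for lo in range(0, n, block):
            hi = min(lo + block, n)
            mask[lo:hi] = restrict(model.decode_many(np.arange(lo, hi, dtype=np.int64)))
        counts_all = np.bincount(state_labels[mask], minlength=len(attractor_cycles))
        total = int(mask.sum())
    else:
        counts_all = np.bincount(state_labels, minlength=len(attractor_cycles))
        total = n

    keep = np.nonzero(counts_all > 0)[0]
    # order attractors by their minimal encoded state for a stable report
    keep = keep[np.argsort([attractor_cycles[k][0] for k in keep])]
    cycles = tuple(
        model.decode_many(np.array(attractor_cycles[k], dtype=np.int64)) for k in keep
    )
    return AttractorLandscape(
        attractors=cycles,
        basin_sizes=counts_all[keep].astype(np.int64),
        total_states=total,
    )


def _all_cyclic(succ: np.ndarray, img: np.ndarray) -> bool:
    """Check that every candidate state returns to itself under succ."""
    cur = succ[img]
    back = cur == img
    # walk at most img.size steps in lockstep (cycles are short in practice)
    for _ in range(img.size):
        if back.all():
            return True
        cur = succ[cur]
        back |= cur == img
    return bool(back.all())


# -- knockouts -----------------------------------------------------------------


def apply_knockout(model: NetworkModel, spec: KnockoutSpec) -> NetworkModel:
    """Return a new model with each clamped node's table made constant.

    Deletion of a network element is modeled as clamping the node to a fixed
    level (its least-active level, 0, for the standard presets); the table
    keeps its regulator structure but outputs the clamp level everywhere, so
    from step 1 on the node holds its clamp level in every trajectory.
    """
    for nid, lev in spec.clamps.items():
        if not 0 <= nid < model.n_nodes:
            raise KeyError(f"unknown node id {nid}")
        if not 0 <= lev < model.nodes[nid].arity:
            raise ValueError(
                f"clamp level {lev} invalid for node {model.nodes[nid].name!r} "
                f"(arity {model.nodes[nid].arity})"
            )
    tables = list(model.tables)
    for nid, lev in spec.clamps.items():
        old = tables[nid]
        tables[nid] = TruthTable(
            node_id=nid,
            regulator_arities=old.regulator_arities,
            outputs=np.full(old.n_rows, lev, dtype=np.int8),
        )
    clamp_names = ",".join(
        f"{model.nodes[nid].name}={lev}" for nid, lev in sorted(spec.clamps.items())
    )
    meta = dict(model.metadata)
    meta["knockout"] = clamp_names
    return NetworkModel(model.nodes, tables, name=f"{model.name}[{clamp_names}]", metadata=meta)
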