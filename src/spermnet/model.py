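"""Core containers for synchronous multi-valued logical networks.

A network is a finite set of discrete-valued nodes.  Node ``i`` carries an
*arity* ``a_i`` (number of levels, 2 for Boolean nodes, 3 for ternary ones),
an ordered list of regulator node ids, and a complete truth table mapping
every combination of regulator levels to the node's next level.  The global
state is a length-``N`` integer vector; synchronous update replaces every
node's level simultaneously by its table output.

States admit a bijective mixed-radix encoding onto ``range(prod(arities))``
(C order: the last node is the least significant digit), which is what makes
exhaustive attractor enumeration practical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NodeSpec", "TruthTable", "NetworkModel"]


@dataclass(frozen=True)
class NodeSpec:
    """One node of a logical network.

    Parameters
    ----------
    id : int
        Index of the node, ``0 <= id < N``.
    name : str
        Human-readable identifier (unique within a model).
    arity : int
        Number of discrete levels the node can take (>= 2).
    level_labels : tuple of str
        One label per level, e.g. ``("off", "on")`` or
        ``("basal", "tonic", "supratonic")``.
    regulators : tuple of int
        Ordered node ids whose current levels determine this node's next
        level.  May include the node itself; duplicates are forbidden.
    """

    id: int
    name: str
    arity: int
    level_labels: tuple[str, ...]
    regulators: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.arity < 2:
            raise ValueError(f"node {self.name!r}: arity must be >= 2, got {self.arity}")
        if len(self.level_labels) != self.arity:
            raise ValueError(
                f"node {self.name!r}: {len(self.level_labels)} level labels for arity {self.arity}"
            )
        if len(set(self.regulators)) != len(self.regulators):
            raise ValueError(f"node {self.name!r}: duplicate regulator ids {self.regulators}")


@dataclass(frozen=True)
class TruthTable:
    """Complete regulatory function of one node.

    ``outputs`` is a flat integer array of length ``prod(regulator arities)``
    laid out in C order over the regulator levels (first regulator most
    significant).  Row ``r`` for regulator levels ``(v_1, .., v_k)`` is
    ``r = ravel_multi_index((v_1, .., v_k), regulator_arities)``.
    """

    node_id: int
    regulator_arities: tuple[int, ...]
    outputs: np.ndarray  # shape (prod(regulator_arities),), small ints

    def __post_init__(self) -> None:
        expected = int(np.prod(self.regulator_arities, dtype=np.int64)) if self.regulator_arities else 1
        out = np.asarray(self.outputs, dtype=np.int8)
        if out.ndim != 1 or out.shape[0] != expected:
            raise ValueError(
                f"truth table for node {self.node_id}: expected {expected} rows, got {out.shape}"
            )
        object.__setattr__(self, "outputs", out)

    @property
    def n_rows(self) -> int:
        return int(self.outputs.shape[0])

    def row_index(self, levels: tuple[int, ...] | np.ndarray) -> int:
        """Mixed-radix row index of one input tuple (regulator order)."""
        return int(np.ravel_multi_index(tuple(np.asarray(levels)), self.regulator_arities))

    def rows(self) -> np.ndarray:
        """All input tuples in row order, shape ``(n_rows, k)``."""
        if not self.regulator_arities:
            return np.zeros((1, 0), dtype=np.int8)
        grids = np.indices(self.regulator_arities).reshape(len(self.regulator_arities), -1).T
        return grids.astype(np.int8)


class NetworkModel:
    """A complete synchronous multi-valued logical network.

    Parameters
    ----------
    nodes : sequence of NodeSpec
        Node roster; ``nodes[i].id`` must equal ``i``.
    tables : sequence of TruthTable
        Exactly one table per node, same order as ``nodes``; each table's
        ``regulator_arities`` must match the arities of the node's regulators.
    name : str
        Free-form model name.
    metadata : dict
        Free-form provenance strings.
    """

    def __init__(self, nodes, tables, name: str = "", metadata: dict | None = None):
        self.nodes: tuple[NodeSpec, ...] = tuple(nodes)
        self.tables: tuple[TruthTable, ...] = tuple(tables)
        self.name = name
        self.metadata = dict(metadata or {})
        self._validate()
        self.arities = np.array([n.arity for n in self.nodes], dtype=np.int64)
        # mixed-radix strides, C order (last node least significant)
        self._strides = np.concatenate(
            [np.cumprod(self.arities[::-1])[::-1][1:], [1]]
        ).astype(np.int64)
        self._name_to_id = {n.name: n.id for n in self.nodes}

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        n = len(self.nodes)
        if len(self.tables) != n:
            raise ValueError(f"{len(self.tables)} tables for {n} nodes")
        names = [nd.name for nd in self.nodes]
        if len(set(names)) != n:
            raise ValueError("node names must be unique")
        for i, nd in enumerate(self.nodes):
            if nd.id != i:
                raise ValueError(f"node at position {i} has id {nd.id}")
            for r in nd.regulators:
                if not 0 <= r < n:
                    raise ValueError(f"node {nd.name!r}: regulator id {r} out of range")
            tab = self.tables[i]
            if tab.node_id != i:
                raise ValueError(f"table at position {i} belongs to node {tab.node_id}")
            reg_ar = tuple(self.nodes[r].arity for r in nd.regulators)
            if tab.regulator_arities != reg_ar:
                raise ValueError(
                    f"node {nd.name!r}: table arities {tab.regulator_arities} "
                    f"!= regulator arities {reg_ar}"
                )
            if tab.outputs.size and (tab.outputs.min() < 0 or tab.outputs.max() >= nd.arity):
                raise ValueError(f"node {nd.name!r}: table output outside range(arity)")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def node_id(self, name: str) -> int:
        try:
            return self._name_to_id[name]
        except KeyError:
            raise KeyError(f"no node named {name!r}") from None

    @property
    def total_states(self) -> int:
        return int(np.prod(self.arities, dtype=np.int64))

    # -- state encoding ----------------------------------------------------

    def validate_state(self, state) -> np.ndarray:
        s = np.asarray(state, dtype=np.int64)
        if s.shape != (self.n_nodes,):
            raise ValueError(f"state shape {s.shape}, expected ({self.n_nodes},)")
        if np.any(s < 0) or np.any(s >= self.arities):
            bad = int(np.argmax((s < 0) | (s >= self.arities)))
            raise ValueError(
                f"state level {s[bad]} invalid for node {self.nodes[bad].name!r} "
                f"(arity {self.nodes[bad].arity})"
            )
        return s

    def encode(self, state) -> int:
        """Mixed-radix integer index of a state (bijective)."""
        s = self.validate_state(state)
        return int(s @ self._strides)

    def decode(self, index: int) -> np.ndarray:
        """Inverse of :meth:`encode`."""
        if not 0 <= index < self.total_states:
            raise ValueError(f"state index {index} outside [0, {self.total_states})")
        out = np.empty(self.n_nodes, dtype=np.int8)
        rem = int(index)
        for i in range(self.n_nodes):
            q, rem = divmod(rem, int(self._strides[i]))
            out[i] = q
        return out

    def decode_many(self, indices: np.ndarray) -> np.ndarray:
        """Vectorized decode: shape ``(m,)`` indices -> ``(m, N)`` levels."""
        idx = np.asarray(indices, dtype=np.int64)
        return ((idx[:, None] // self._strides[None, :]) % self.arities[None, :]).astype(np.int8)

    def encode_many(self, states: np.ndarray) -> np.ndarray:
        s = np.asarray(states, dtype=np.int64)
        return s @ self._strides

    # -- misc --------------------------------------------------------------

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<NetworkModel {self.name!r}: {self.n_nodes} nodes, "
            f"{self.total_states} states>"
        )


# re-exported convenience ------------------------------------------------------

def table_from_function(model_nodes, node_id: int, fn) -> TruthTable:
    """Build a complete TruthTable by evaluating ``fn`` on every input tuple.

    ``fn`` receives one keyword argument per regulator, named after the
    regulator node, and returns the output level.  Used by model builders
    and test fixtures; guarantees completeness by construction.
    """
    node = model_nodes[node_id]
    reg_ar = tuple(model_nodes[r].arity for r in node.regulators)
    reg_names = [model_nodes[r].name for r in node.regulators]
    if reg_ar:
        grids = np.indices(reg_ar).reshape(len(reg_ar), -1).T
    else:
        grids = np.zeros((1, 0), dtype=int)
    outputs = np.empty(grids.shape[0], dtype=np.int8)
    for row, levels in enumerate(grids):
        outputs[row] = fn(**dict(zip(reg_names, (int(v) for v in levels))))
    return TruthTable(node_id=node_id, regulator_arities=reg_ar, outputs=outputs)
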