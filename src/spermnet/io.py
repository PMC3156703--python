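"""Model-file reading/validation/writing and trajectory export.

The model file is a JSON document::

    {
      "name": ...,
      "nodes": [{"name", "arity", "levels", "regulators": [node names]}, ...],
      "tables": {node name: [[input levels..., output], ...], ...},
      "metadata": {...}
    }

Rows list the input tuple in regulator order followed by the output level;
tables must be complete (every combination exactly once).  Validation is
structural and reports the offending node and row.  All writes are atomic
(temp file then rename), so partial outputs never parse.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np

from .dynamics import Trajectory
from .model import NetworkModel, NodeSpec, TruthTable

__all__ = ["read_model", "write_model", "model_hash", "write_raster", "read_raster"]


class ModelFormatError(ValueError):
    """Malformed or structurally invalid model file."""


def _atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_model(path: str | Path) -> NetworkModel:
    """Load and fully validate a JSON model file."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ModelFormatError(f"{path}: not valid JSON: {e}") from e
    for key in ("name", "nodes", "tables"):
        if key not in doc:
            raise ModelFormatError(f"{path}: missing top-level key {key!r}")
    name_to_id = {}
    for i, nd in enumerate(doc["nodes"]):
        for key in ("name", "arity", "levels", "regulators"):
            if key not in nd:
                raise ModelFormatError(f"node #{i}: missing key {key!r}")
        if nd["name"] in name_to_id:
            raise ModelFormatError(f"duplicate node name {nd['name']!r}")
        name_to_id[nd["name"]] = i
    nodes = []
    for i, nd in enumerate(doc["nodes"]):
        try:
            regs = tuple(name_to_id[r] for r in nd["regulators"])
        except KeyError as e:
            raise ModelFormatError(f"node {nd['name']!r}: unknown regulator {e.args[0]!r}") from e
        try:
            nodes.append(
                NodeSpec(
                    id=i,
                    name=nd["name"],
                    arity=int(nd["arity"]),
                    level_labels=tuple(nd["levels"]),
                    regulators=regs,
                )
            )
        except ValueError as e:
            raise ModelFormatError(str(e)) from e

    tables = []
    for i, nd in enumerate(nodes):
        rows = doc["tables"].get(nd.name)
        if rows is None:
            raise ModelFormatError(f"node {nd.name!r}: no truth table")
        reg_ar = tuple(nodes[r].arity for r in nd.regulators)
        k = len(reg_ar)
        expected = int(np.prod(reg_ar)) if reg_ar else 1
        outputs = np.full(expected, -1, dtype=np.int8)
        for row in rows:
            if len(row) != k + 1:
                raise ModelFormatError(
                    f"node {nd.name!r}: row {row} should have {k} inputs + 1 output"
                )
            ins, out = row[:k], row[k]
            for v, a in zip(ins, reg_ar):
                if not 0 <= v < a:
                    raise ModelFormatError(f"node {nd.name!r}: input level {v} out of range in {row}")
            ridx = int(np.ravel_multi_index(tuple(ins), reg_ar)) if k else 0
            if outputs[ridx] != -1:
                raise ModelFormatError(f"node {nd.name!r}: duplicate row for inputs {tuple(ins)}")
            outputs[ridx] = out
        if (outputs == -1).any():
            missing = int(np.nonzero(outputs == -1)[0][0])
            tup = tuple(int(v) for v in np.unravel_index(missing, reg_ar)) if k else ()
            raise ModelFormatError(
                f"node {nd.name!r}: incomplete truth table, missing input tuple {tup} "
                f"({int((outputs == -1).sum())} of {expected} rows absent)"
            )
        try:
            tables.append(TruthTable(node_id=i, regulator_arities=reg_ar, outputs=outputs))
        except ValueError as e:
            raise ModelFormatError(str(e)) from e

    try:
        return NetworkModel(nodes, tables, name=doc["name"], metadata=doc.get("metadata", {}))
    except ValueError as e:
        raise ModelFormatError(str(e)) from e


def _model_doc(model: NetworkModel) -> dict:
    nodes = [
        {
            "name": nd.name,
            "arity": nd.arity,
            "levels": list(nd.level_labels),
            "regulators": [model.nodes[r].name for r in nd.regulators],
        }
        for nd in model.nodes
    ]
    tables = {}
    for nd, tab in zip(model.nodes, model.tables):
        rows = tab.rows()
        tables[nd.name] = [
            [int(v) for v in row] + [int(out)] for row, out in zip(rows, tab.outputs)
        ]
    return {"name": model.name, "nodes": nodes, "tables": tables, "metadata": model.metadata}


def write_model(model: NetworkModel, path: str | Path) -> None:
    """Serialize a model to the JSON model format (atomic write)."""
    doc = _model_doc(model)
    text = json.dumps(doc, separators=(",", ":"), sort_keys=False) + "\n"
    _atomic_write_text(path, text)


def model_hash(model: NetworkModel) -> str:
    """Content hash of the canonicalized model JSON (pins frozen tables)."""
    doc = _model_doc(model)
    blob = json.dumps(doc, separators=(",", ":"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# -- raster export -------------------------------------------------------------

#: color classes used for the image raster, by node kind
_TERNARY_COLORS = {
    "V": {0: (0.1, 0.3, 0.9), 1: (0.0, 0.0, 0.0), 2: (0.9, 0.1, 0.1)},  # blue/black/red
    "default3": {0: (0.0, 0.0, 0.0), 1: (0.9, 0.8, 0.1), 2: (0.9, 0.1, 0.1)},  # black/yellow/red
}
_BINARY_COLORS = {0: (0.0, 0.0, 0.0), 1: (0.1, 0.8, 0.2)}  # black/green


def write_raster(
    traj: Trajectory,
    path: str | Path,
    format: str = "text",
    model: NetworkModel | None = None,
) -> None:
    """Export a trajectory as a grid: time down the rows, nodes across.

    ``format="text"`` writes digit levels (one row per step, no separators),
    re-parseable with :func:`read_raster`.  ``format="image"`` writes a PNG
    using the published color semantics: binary nodes black/green
    (off/on); membrane potential blue/black/red (hyperpolarized/resting/
    depolarized); other ternary nodes black/yellow/red (e.g. basal/tonic/
    supratonic calcium).  The image format requires ``model`` for names.
    """
    path = Path(path)
    if format == "text":
        lines = ["".join(str(int(v)) for v in row) for row in traj.states]
        _atomic_write_text(path, "\n".join(lines) + "\n")
        return
    if format != "image":
        raise ValueError(f"unknown raster format {format!r}")
    if model is None:
        raise ValueError("image raster needs the model for node arities/names")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = traj.states
    t, n = arr.shape
    rgb = np.zeros((t, n, 3))
    for j, nd in enumerate(model.nodes):
        if nd.arity == 2:
            cmap = _BINARY_COLORS
        elif nd.name == "V":
            cmap = _TERNARY_COLORS["V"]
        else:
            cmap = _TERNARY_COLORS["default3"]
        for lev, color in cmap.items():
            rgb[arr[:, j] == lev, j] = color
    fig, ax = plt.subplots(figsize=(max(4, n * 0.35), max(3, t * 0.18)))
    ax.imshow(rgb, interpolation="nearest", aspect="auto")
    ax.set_xticks(range(n))
    ax.set_xticklabels(model.node_names, rotation=90, fontsize=7)
    ax.set_ylabel("time step")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def read_raster(path: str | Path) -> np.ndarray:
    """Parse a text raster back into a (time, nodes) level matrix."""
    lines = Path(path).read_text().strip().splitlines()
    return np.array([[int(c) for c in line] for line in lines], dtype=np.int8)
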