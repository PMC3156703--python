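"""Calcium-centric phenotype readouts and the in-silico knockout screen.

The discrete calcium node summarizes the pathway's output: its supratonic
level (2) marks the transient Ca2+ peaks that drive flagellar turning.  A
trajectory's phenotype is the attractor period, how many attractor states
are supratonic, and the delay from stimulation to the first supratonic
state — the quantities the published deletion experiments compare.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .dynamics import KnockoutSpec, Trajectory, apply_knockout, simulate, successors
from .model import NetworkModel

__all__ = [
    "PhenotypeSummary",
    "MeanCaTimecourse",
    "summarize_phenotype",
    "mean_ca_timecourse",
    "knockout_screen",
]


@dataclass(frozen=True)
class PhenotypeSummary:
    """Calcium readout of one trajectory."""

    period: int
    supratonic_count: int
    supratonic_fraction: Fraction
    transient_length: int
    delay_to_first_supratonic: int | None  # None encodes "never"
    oscillating: bool  # attractor visits >= 2 distinct Ca levels

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["supratonic_fraction"] = float(self.supratonic_fraction)
        d["delay_to_first_supratonic"] = (
            "never" if self.delay_to_first_supratonic is None
            else self.delay_to_first_supratonic
        )
        return d


@dataclass(frozen=True)
class MeanCaTimecourse:
    """Per-step ensemble mean of the Ca level over random initial states."""

    mean_ca: np.ndarray
    n_ensemble: int
    seed: int


def summarize_phenotype(traj: Trajectory, ca_node: int, ca_arity: int = 3) -> PhenotypeSummary:
    """Phenotype of a simulated trajectory.

    ``ca_node`` must be the ternary calcium node; the supratonic level is the
    top level (2).  The delay counts the initial state as t = 0 and is None
    when no visited state (transient or attractor) is supratonic.
    """
    if ca_arity != 3:
        raise ValueError("calcium node must be ternary (basal/tonic/supratonic)")
    ca_traj = traj.levels_of(ca_node)
    ca_cycle = traj.attractor[:, ca_node]
    supra = int((ca_cycle == 2).sum())
    hits = np.nonzero(ca_traj == 2)[0]
    if hits.size:
        delay = int(hits[0])
    elif supra:  # supratonic occurs on the cycle but trajectory array covers it
        delay = int(traj.transient_length + int(np.nonzero(ca_cycle == 2)[0][0]))
    else:
        delay = None
    return PhenotypeSummary(
        period=traj.period,
        supratonic_count=supra,
        supratonic_fraction=Fraction(supra, traj.period),
        transient_length=traj.transient_length,
        delay_to_first_supratonic=delay,
        oscillating=len(np.unique(ca_cycle)) >= 2,
    )


def mean_ca_timecourse(
    model: NetworkModel,
    n_ensemble: int,
    horizon: int,
    seed: int,
    speract_on: bool = True,
) -> MeanCaTimecourse:
    """Ensemble-average Ca level per time step over random initial states.

    Initial states are uniform over the speract-on sector (or the full space
    when ``speract_on`` is False); the run is bit-reproducible for a fixed
    seed.  ``mean_ca[t]`` is the mean calcium level at step ``t`` (t = 0 is
    the initial state), on the 0-2 discrete scale.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if n_ensemble < 1:
        raise ValueError("n_ensemble must be >= 1")
    rng = np.random.default_rng(seed)
    cols = [rng.integers(0, int(a), size=n_ensemble) for a in model.arities]
    states = np.stack(cols, axis=1).astype(np.int8)
    if speract_on:
        states[:, model.node_id("speract")] = 1
    ca = model.node_id("Ca")
    idx = model.encode_many(states)
    out = np.empty(horizon + 1)
    out[0] = states[:, ca].mean()
    for t in range(1, horizon + 1):
        idx = successors(model, idx)
        out[t] = model.decode_many(idx)[:, ca].mean()
    return MeanCaTimecourse(mean_ca=out, n_ensemble=n_ensemble, seed=seed)


def knockout_screen(
    model: NetworkModel,
    presets: dict[str, KnockoutSpec],
    init,
    max_steps: int = 100_000,
) -> pd.DataFrame:
    """Phenotype table for wild type plus each knockout preset.

    Each condition is simulated from the same initial state; the wild-type
    row comes first.  Results are pure functions of (model, init), so the
    table is independent of preset order.
    """
    ca = model.node_id("Ca")
    rows = []
    conditions = [("wild_type", None)] + sorted(presets.items())
    for name, spec in conditions:
        m = model if spec is None else apply_knockout(model, spec)
        summ = summarize_phenotype(simulate(m, init, max_steps), ca)
        rows.append({"condition": name, **summ.as_dict()})
    return pd.DataFrame(rows).set_index("condition")
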