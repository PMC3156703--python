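"""The 22-node speract-activated Ca2+ signaling network of sea urchin sperm.

Speract, a decapeptide from *S. purpuratus* egg jelly, binds its flagellar
receptor (SR) and triggers, via guanylate cyclase (GC) and cGMP, the opening
of a cGMP-gated K+ channel (KCNG).  The resulting K+ permeability (dK)
hyperpolarizes the membrane potential (V), which activates Na+/Ca2+ exchange
(NCE), Na+/H+ exchange (NHE, raising intracellular pH), the HCN channel, and
removes inactivation from the low- and high-voltage-activated Ca2+ channels
(LVA, HVA).  Repolarization opens those channels, calcium surges to the
supratonic level, and Ca2+-dependent Cl- and K+ channels (CaCC, CaKC)
re-hyperpolarize the membrane, restarting the cycle; constitutive extrusion
(CaP pumps, NCE) restores basal calcium.  Eighteen nodes are binary; the
membrane potential (hyperpolarized/resting/depolarized), the LVA and HVA
channels (inactive/closed/open) and calcium (basal/tonic/supratonic) are
ternary.

The authors' original truth tables were distributed through a web page that
no longer exists; the tables packaged here are reconstructed from the
documented interaction logic and calibrated until every published dynamical
outcome of the model holds (wild-type period-4 attractor with supratonic
fraction 1/4, an 11 = 6 + 5 attractor landscape with four period-4 and one
period-8 active attractor, the six node-deletion phenotypes, and critical
Derrida dynamics).  Equivalence with the original model is claimed only at
the level of those published outcomes.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .dynamics import KnockoutSpec
from .model import NetworkModel, NodeSpec, TruthTable, table_from_function

__all__ = [
    "NODE_ORDER",
    "build_speract_model",
    "wildtype_basal_init",
    "preset_knockouts",
    "packaged_model_path",
    "packaged_presets_path",
]

#: node roster in index order (18 binary + 4 ternary: V, HVA, LVA, Ca)
NODE_ORDER = (
    "speract", "SR", "GC", "cGMP", "KCNG", "dK", "V", "NCE", "NHE", "pHi",
    "sAC", "cAMP", "PDE", "HCN", "cAMPCC", "HVA", "LVA", "Ca", "CaCC",
    "CaKC", "CaP", "dCl",
)

_BIN = ("off", "on")
_LEVELS = {
    "V": ("hyperpolarized", "resting", "depolarized"),
    "HVA": ("inactive", "closed", "open"),
    "LVA": ("inactive", "closed", "open"),
    "Ca": ("basal", "tonic", "supratonic"),
}

#: regulators by name, in table order
_REGULATORS = {
    "speract": ("speract",),            # constant input: copies itself
    "SR": ("speract",),
    "GC": ("SR", "pHi"),
    "cGMP": ("GC",),
    "KCNG": ("cGMP",),
    "dK": ("KCNG", "CaKC"),
    "V": ("dK", "CaKC", "dCl", "HCN", "cAMPCC", "LVA", "HVA"),
    "NCE": ("V",),
    "NHE": ("V",),
    "pHi": ("NHE",),
    "sAC": ("pHi",),
    "cAMP": ("sAC", "PDE", "cAMP"),
    "PDE": ("speract",),
    "HCN": ("V", "cAMP"),      # mode 1 adds cGMP
    "cAMPCC": ("cAMP",),
    "HVA": ("V", "Ca", "cAMP", "HVA"),
    "LVA": ("V", "Ca", "LVA"),
    "Ca": ("LVA", "HVA", "Ca", "speract", "NCE", "CaP", "cAMPCC"),
    "CaCC": ("Ca",),
    "CaKC": ("Ca",),
    "CaP": ("CaP",),                    # constitutive: constant output
    "dCl": ("CaCC",),
}

# Calibrated rule parameters.  Each knob is a discrete modeling choice left
# open by the documented interaction logic; the values below are the frozen
# calibration (see docs/methods.md for their meaning and rationale).
_RULES: dict = {
    # V: weighted hyperpolarizing vs depolarizing drives, thresholds on the
    # difference.  K+ permeability and the Ca-activated K+ channel carry
    # unit weight; Cl- permeability weighs double (calibrated dominance);
    # a weak constitutive receptor current depolarizes while speract is bound.
    "w_dk": 1, "w_cakc": 1, "w_dcl": 2, "w_hcn": 1, "w_campcc": 1,
    "w_lva": 1, "w_hva": 2, "w_sp_v": 1, "th_hyper": 1, "th_depol": 1,
    "v_integrator": 0, "v_relax": 0,
    "v_k_dominance": 1,          # K+ conductance alone collapses a resting V
    "v_tie_lva_depol": 1,        # open T-type prevails at balanced drive (V=1)
    # LVA (T-type): rebound opening after hyperpolarization; window opening
    # at rest in an alkalinized, calcium-basal cell; recovery from
    # inactivation requires hyperpolarization and is calcium-gated.
    "lva_rest_recovery": 0,      # closed <- inactive at resting V
    "lva_phi_recovery": 1,       # pHi-assisted recovery at tonic Ca
    "lva_open_at_rest": 0,       # open directly from closed at resting V
    "lva_recovery_ca_max": 0,    # max Ca level at which 0->1 recovery works
    "lva_closed_survives_depol": 1,
    "lva_open_after_hyper": 1,   # level reached by an open channel at V=0
    "lva_open_at_rest_next": 1,  # level reached by an open channel at V=1
    "lva_window": 1,             # window opening at rest (basal Ca, high pHi)
    # HVA (L-type): opens on depolarization with calcium-dependent
    # facilitation (needs tonic Ca unless cAMP-primed) and is blocked by
    # supratonic calcium; recovery is calcium-gated with cAMP override.
    "hva_open_ca_max": 1,        # max Ca at which closed->open fires at V=2
    "hva_open_needs_tonic": 1,   # opening requires tonic Ca or cAMP priming
    "hva_recovery_ca_max": 0,    # max Ca at which 0->1 recovery works at V=0
    "hva_camp_recovery": 1,      # cAMP facilitation overrides the Ca gate
    "hva_open_after_depol": 0,   # fate of an open channel at sustained V=2
    "hva_open_at_rest_next": 1,  # fate of an open channel at V=1
    # Ca: net flux score -> level; the supratonic level requires an open
    # Ca2+ channel; extrusion pathways saturate (max, not sum).
    "ca_w_lva": 3, "ca_w_hva": 1, "ca_w_sp": 2, "ca_w_campcc": 0,
    "ca_w_nce": 1, "ca_w_cap": 1,
    "ca_v_gate": 0,              # LVA flux weight drops by 1 unless V hyperpolarized
    "ca_hva_campcc_shunt": 0,    # HVA flux drops by 1 at V<2 when cAMPCC is open
    "ca_tonic_needs_ca": 0,      # net flux +1 gives the tonic level directly
    "ca_surge_needs_channel": 1, # supratonic requires an open Ca2+ channel
    "ca_efflux_max": 1,          # combine NCE/CaP efflux by max instead of sum
    # cascade wiring
    "gc_phi_inhibition": 0,      # pHi inhibition of GC not in the final tables
    "phi_persistent": 0,
    "hcn_mode": 1,               # HCN needs a cyclic nucleotide in addition to V=0
    "cakc_needs_v": 0,
    "cakc_persist": 0,
    "cakc_mode": "v2tonic",      # CaKC opens on depolarization at >= tonic Ca
    "cacc_mode": "supra",        # CaCC opens on supratonic Ca
    "pde_mode": "speract",       # PDE active whenever the pathway is engaged
}


def _clip(x: int, lo: int = 0, hi: int = 2) -> int:
    return max(lo, min(hi, x))


def _rule_functions(p: dict) -> dict:
    """Per-node update rules (keyword args named after regulators)."""

    def v_rule(dK, CaKC, dCl, HCN, cAMPCC, LVA, HVA, V=1, speract=0):
        if (
            p["v_k_dominance"]
            and V == 1
            and dK
            and not (CaKC or dCl or HCN or cAMPCC or LVA == 2 or HVA == 2)
        ):
            # with K+ conductance open and no depolarizing conductance at
            # all, the potential collapses toward E_K
            return 0
        h = p["w_dk"] * dK + p["w_cakc"] * CaKC + p["w_dcl"] * dCl
        d = (
            p["w_hcn"] * HCN
            + p["w_campcc"] * cAMPCC
            + p["w_lva"] * (LVA == 2)
            + p["w_hva"] * (HVA == 2)
            + p["w_sp_v"] * speract
        )
        if p["v_integrator"]:
            if h - d >= p["th_hyper"]:
                return max(V - 1, 0)
            if d - h >= p["th_depol"]:
                return min(V + 1, 2)
            if p["v_relax"]:
                return V + (1 if V < 1 else (-1 if V > 1 else 0))
            return V
        if h - d >= p["th_hyper"]:
            return 0
        if d - h >= p["th_depol"]:
            return 2
        if p["v_tie_lva_depol"] and h == d and LVA == 2 and V == 1:
            return 2  # at balanced drive an open T-type current prevails
        return 1

    def lva_rule(V, Ca, LVA, pHi=0):
        if LVA == 0:  # inactivated: recovery only by (gated) hyperpolarization
            if V == 0 and Ca <= p["lva_recovery_ca_max"]:
                return 1
            if p["lva_phi_recovery"] and V == 0 and Ca == 1 and pHi == 1:
                return 1  # alkalinization promotes recovery at tonic Ca
            if V == 1 and p["lva_rest_recovery"]:
                return 1
            return 0
        if LVA == 1:  # closed / primed
            if V == 0:
                return 2  # rebound opening driven by hyperpolarization
            if V == 1:
                if p["lva_window"] and Ca == 0 and pHi == 1:
                    return 2  # window current: basal Ca, alkalinized cell
                return 2 if p["lva_open_at_rest"] else 1
            return 1 if p["lva_closed_survives_depol"] else 0
        # LVA == 2, open: brief opening, then deactivation/inactivation
        if V == 0:
            return p["lva_open_after_hyper"]
        if V == 1:
            return p["lva_open_at_rest_next"]
        return 0  # inactivates at sustained depolarization

    def hva_rule(V, Ca, cAMP, HVA):
        if HVA == 0:
            # recovery from inactivation at hyperpolarized V; blocked by
            # elevated Ca unless the channel is cAMP/PKA-facilitated
            if V == 0 and Ca <= p["hva_recovery_ca_max"]:
                return 1
            mode = p["hva_camp_recovery"]
            if cAMP and mode:
                if mode == 1 and V == 0:
                    return 1
                if mode == 2 and V <= 1:
                    return 1
                if mode == 3 and V <= 1 and Ca == 0:
                    return 1
                if mode == 4 and V == 0 and Ca == 0:
                    return 1
            return 0
        if HVA == 1:
            if V == 2 and Ca <= p["hva_open_ca_max"]:
                if p["hva_open_needs_tonic"] and Ca == 0 and not cAMP:
                    return 1  # no calcium-dependent facilitation at basal Ca
                return 2  # opens on depolarization unless Ca-blocked
            return 1
        # open
        if V == 2:
            if p["hva_open_after_depol"] == "ca":
                return 0 if Ca == 2 else 2  # calcium-dependent inactivation
            return p["hva_open_after_depol"]
        if V == 1:
            return p["hva_open_at_rest_next"]
        return 1  # deactivates (closes) on hyperpolarization

    def ca_rule(LVA, HVA, Ca=None, V=None, speract=0, NCE=0, CaP=0, cAMPCC=0):
        w_lva = p["ca_w_lva"]
        if p["ca_v_gate"] and V != 0:
            w_lva -= 1  # reduced Ca driving force away from hyperpolarization
        w_hva = p["ca_w_hva"]
        if p["ca_hva_campcc_shunt"] and cAMPCC and V is not None and V != 2:
            w_hva -= 1  # HVA flux shunted at sub-depolarized V when cAMPCC is on
        influx = (
            w_lva * (LVA == 2)
            + w_hva * (HVA == 2)
            + p["ca_w_sp"] * speract
            + p["ca_w_campcc"] * cAMPCC
        )
        if p["ca_efflux_max"]:
            efflux = max(p["ca_w_nce"] * NCE, p["ca_w_cap"] * CaP)
        else:
            efflux = p["ca_w_nce"] * NCE + p["ca_w_cap"] * CaP
        net = influx - efflux
        if net >= 2:
            if p["ca_surge_needs_channel"] and not (LVA == 2 or HVA == 2 or cAMPCC):
                if p["ca_tonic_needs_ca"] and Ca is not None:
                    return 1 if Ca >= 1 else 0
                return 1
            return 2
        if net == 1:
            if p["ca_tonic_needs_ca"] and Ca is not None:
                return 1 if Ca >= 1 else 0
            return 1
        if net == 0:
            return _clip(Ca - 1) if Ca is not None else 0
        return 0

    def phi_rule(NHE, pHi=0):
        if p["phi_persistent"]:
            return int(bool(NHE or pHi))
        return NHE

    def pde_rule(speract=None, pHi=None):
        if p["pde_mode"] == "const1":
            return 1
        if p["pde_mode"] == "phi":
            return pHi
        return speract

    def cakc_rule(Ca, V=None, CaKC=None):
        if p["cakc_mode"] == "v2tonic":
            # voltage-dependent Ca-activated K+ channel: opens on depolarization
            # once calcium is at least tonic
            return int(Ca >= 1 and V == 2)
        if p["cakc_persist"]:
            return int(Ca == 2 or (CaKC == 1 and Ca >= 1))
        if p["cakc_needs_v"]:
            return int(Ca == 2 and V >= 1)
        return int(Ca == 2)

    def cacc_rule(Ca, V=None):
        if p["cacc_mode"] == "v2tonic":
            return int(Ca >= 1 and V == 2)
        return int(Ca == 2)

    return {
        "speract": lambda speract: speract,
        "SR": lambda speract: speract,
        "GC": (lambda SR, pHi: int(SR and not pHi)) if p["gc_phi_inhibition"] else (lambda SR: int(SR)),
        "cGMP": lambda GC: GC,
        "KCNG": lambda cGMP: cGMP,
        "dK": lambda KCNG, CaKC: int(KCNG or CaKC),
        "V": v_rule,
        "NCE": lambda V: int(V == 0),
        "NHE": lambda V: int(V == 0),
        "pHi": phi_rule,
        "sAC": lambda pHi: pHi,
        "cAMP": lambda sAC, PDE, cAMP: int((not PDE) and (sAC or cAMP)),
        "PDE": pde_rule,
        "HCN": (lambda V, cGMP, cAMP: int(V == 0 and (cGMP or cAMP))) if p["hcn_mode"] else (lambda V, cAMP: int(V == 0 or cAMP)),
        "cAMPCC": lambda cAMP: cAMP,
        "HVA": hva_rule,
        "LVA": lva_rule,
        "Ca": ca_rule,
        "CaCC": cacc_rule,
        "CaKC": cakc_rule,
        "CaP": lambda CaP: 1,
        "dCl": lambda CaCC: CaCC,
    }


def _build_from_rules(rules_params: dict | None = None) -> NetworkModel:
    p = dict(_RULES)
    if rules_params:
        p.update(rules_params)
    regulators = dict(_REGULATORS)
    if not p["gc_phi_inhibition"]:
        regulators["GC"] = ("SR",)
    if p["v_integrator"] or p["v_k_dominance"]:
        regulators["V"] = regulators["V"] + ("V",)
    if p["w_sp_v"]:
        regulators["V"] = regulators["V"] + ("speract",)
    if p["ca_v_gate"]:
        # V replaces the Ca self-input; the rule becomes memoryless
        regulators["Ca"] = ("LVA", "HVA", "V", "speract", "NCE", "CaP", "cAMPCC")
    if p["phi_persistent"]:
        regulators["pHi"] = ("NHE", "pHi")
    if p["pde_mode"] == "phi":
        regulators["PDE"] = ("pHi",)
    if p["pde_mode"] == "const1":
        regulators["PDE"] = ("PDE",)
    if p["cakc_needs_v"]:
        regulators["CaKC"] = ("Ca", "V")
    if p["cakc_persist"]:
        regulators["CaKC"] = ("Ca", "CaKC")
    if p["cakc_mode"] == "v2tonic":
        regulators["CaKC"] = ("Ca", "V")
    if p["cacc_mode"] == "v2tonic":
        regulators["CaCC"] = ("Ca", "V")
    if p["hcn_mode"]:
        regulators["HCN"] = ("V", "cGMP", "cAMP")
    if p["lva_window"]:
        regulators["LVA"] = ("V", "Ca", "LVA", "pHi")

    name_to_id = {n: i for i, n in enumerate(NODE_ORDER)}
    nodes = []
    for i, nm in enumerate(NODE_ORDER):
        arity = 3 if nm in _LEVELS else 2
        labels = _LEVELS.get(nm, _BIN)
        regs = tuple(name_to_id[r] for r in regulators[nm])
        nodes.append(NodeSpec(id=i, name=nm, arity=arity, level_labels=labels, regulators=regs))

    fns = _rule_functions(p)
    tables = []
    for i, nm in enumerate(NODE_ORDER):
        fn = fns[nm]
        if nm == "PDE" and p["pde_mode"] == "const1":
            tables.append(table_from_function(nodes, i, lambda PDE: 1))
        else:
            tables.append(table_from_function(nodes, i, fn))
    return NetworkModel(
        nodes,
        tables,
        name="speract-ca-signaling",
        metadata={"organism": "Strongylocentrotus purpuratus sperm flagellum"},
    )


def build_speract_model() -> NetworkModel:
    """The packaged 22-node speract signaling network (frozen calibration)."""
    return _build_from_rules()


def wildtype_basal_init(model: NetworkModel, speract: int = 1) -> np.ndarray:
    """Basal initial condition: speract at the given level, all else at 0."""
    if speract not in (0, 1):
        raise ValueError("speract level must be 0 or 1")
    s = np.zeros(model.n_nodes, dtype=np.int8)
    s[model.node_id("speract")] = speract
    return s


def packaged_model_path() -> Path:
    """Path of the packaged speract model JSON (the frozen reference tables)."""
    return Path(resources.files("spermnet") / "data" / "speract_model.json")


def packaged_presets_path() -> Path:
    """Path of the packaged knockout presets JSON."""
    return Path(resources.files("spermnet") / "data" / "presets.json")


#: the six node deletions studied computationally (clamp-to-0 semantics)
_PRESET_NAMES = ("dK", "LVA", "PDE", "CaCC", "CaKC", "HVA")


def preset_knockouts(model: NetworkModel) -> dict[str, KnockoutSpec]:
    """Named knockout presets used in the published deletion experiments."""
    return {nm: KnockoutSpec(clamps={model.node_id(nm): 0}) for nm in _PRESET_NAMES}
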