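"""Builders for the elementary ratio-recognition unit and its population extensions.

The elementary unit is a feed-forward competition circuit: two compound ORN
sources (one per pheromone component) excite their ipsilateral specialist
local neurons (LNa, LNb) and a shared generalist (LNc); the three LNs inhibit
each other all-to-all; the generalist inhibits an intermediary inhibitory
neuron (LNi) which tonically inhibits the projection neuron (PN).  When the
blend is at the target ratio the generalist wins the competition, LNi is
silenced, and the PN is disinhibited — a discrete 'ratio detected' signal.

Two population extensions are provided: a *stacked* arrangement of independent
elementary LN triplets converging on a single LNi/PN, and a *grouped*
arrangement in which each LN is replaced by a glomerulus of like copies with
all-to-all inhibition between (not within) glomeruli.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .synapses import SynapseParams, DEFAULT_T_RELEASE

__all__ = [
    "ConductanceSet",
    "Cell",
    "ORNSource",
    "Synapse",
    "NetworkSpec",
    "build_elementary",
    "build_stacked",
    "build_grouped",
    "TABLE1_CONDUCTANCES",
    "BASELINE_INTER_LN_G",
    "E_REV_EXC",
    "E_REV_INH",
    "SPONTANEOUS_CURRENT_NA",
]

E_REV_EXC = 0.0     # mV, ORN→LN synapses
E_REV_INH = -80.0   # mV, all LN/LNi output synapses (GABAergic)
SPONTANEOUS_CURRENT_NA = 0.1  # constant drive into LNi and PN

#: annealed conductance sets (µS) per ORN→LN convergence rate, conductance model
TABLE1_CONDUCTANCES: dict[int, "ConductanceSet"] = {}

#: inter-LN conductance used in the uniform-baseline perturbation experiment
BASELINE_INTER_LN_G = 0.18


@dataclass(frozen=True)
class ConductanceSet:
    """The five optimizable synaptic strengths plus the fixed disinhibition pathway (µS).

    The symmetric 1:1 target ratio fixes g_ORNa→LNa = g_ORNb→LNb (= g_orn_lnsp)
    and g_ORNa→LNc = g_ORNb→LNc (= g_orn_lngen).  Inter-LN strengths follow the
    inbound/transverse/outbound naming: g_lni = g(LNsp→LNgen),
    g_lnt = g(LNsp→LNsp), g_lno = g(LNgen→LNsp).
    """

    g_orn_lnsp: float
    g_orn_lngen: float
    g_lni: float
    g_lnt: float
    g_lno: float
    g_lnc_lni: float = 0.5
    g_lni_pn: float = 0.5

    def __post_init__(self) -> None:
        if min(asdict(self).values()) < 0:
            raise ValueError("conductances must be non-negative")

    def as_free_vector(self) -> np.ndarray:
        """The five annealed parameters in canonical order."""
        return np.array([self.g_orn_lnsp, self.g_orn_lngen,
                         self.g_lni, self.g_lnt, self.g_lno])

    @classmethod
    def from_free_vector(cls, x, g_lnc_lni: float = 0.5, g_lni_pn: float = 0.5) -> "ConductanceSet":
        x = np.maximum(np.asarray(x, dtype=float), 0.0)
        return cls(*x, g_lnc_lni=g_lnc_lni, g_lni_pn=g_lni_pn)


TABLE1_CONDUCTANCES.update({
    200: ConductanceSet(0.023, 0.013, 0.185, 0.185, 0.184),
    500: ConductanceSet(0.094, 0.072, 0.490, 0.500, 0.347),
    1000: ConductanceSet(0.103, 0.074, 0.499, 0.389, 0.386),
})


@dataclass(frozen=True)
class Cell:
    """One Hodgkin–Huxley cell of the circuit."""

    name: str
    role: str          # 'LN' | 'LNi' | 'PN'
    group: str = ""    # competition group for LNs: 'a' | 'b' | 'c'
    i_inj: float = 0.0  # nA


@dataclass(frozen=True)
class ORNSource:
    """One compound Poisson ORN population."""

    name: str
    component: str     # pheromone component driving it: 'a' | 'b'
    n_orn: int         # ORN→LN convergence (population size)


@dataclass(frozen=True)
class Synapse:
    pre: str
    post: str
    params: SynapseParams


@dataclass
class NetworkSpec:
    """Explicit cell/synapse graph of one arrangement."""

    arrangement: str   # 'elementary' | 'stacked' | 'grouped'
    orn_sources: list[ORNSource] = field(default_factory=list)
    cells: list[Cell] = field(default_factory=list)
    synapses: list[Synapse] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        """All model cells, compound ORN sources included."""
        return len(self.orn_sources) + len(self.cells)

    def cell_names(self) -> list[str]:
        return [c.name for c in self.cells]

    def ln_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for c in self.cells:
            if c.role == "LN":
                groups.setdefault(c.group, []).append(c.name)
        return groups

    def positive_weight_synapses(self) -> list[Synapse]:
        return [s for s in self.synapses if s.params.g > 0]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check the feed-forward layering and synapse sign conventions."""
        layer = {s.name: 0 for s in self.orn_sources}
        for c in self.cells:
            layer[c.name] = {"LN": 1, "LNi": 2, "PN": 3}[c.role]
        for syn in self.synapses:
            if syn.pre not in layer or syn.post not in layer:
                raise ValueError(f"synapse references unknown cell: {syn.pre}->{syn.post}")
            lp, lq = layer[syn.pre], layer[syn.post]
            if lp == 0 and lq != 1:
                raise ValueError("ORNs may only contact LNs")
            if lp == 0 and syn.params.e_rev <= E_REV_INH:
                raise ValueError("ORN→LN synapses must be excitatory")
            if lp >= 1 and syn.params.e_rev > -60.0:
                raise ValueError("LN/LNi output synapses must be inhibitory")
            if lp >= 1 and lq < lp:
                raise ValueError(f"feedback edge {syn.pre}->{syn.post} violates feed-forward design")
            if lp == 1 and lq not in (1, 2):
                raise ValueError("LNs may only contact LNs and LNi")
            if lp == 2 and lq != 3:
                raise ValueError("LNi may only contact the PN")
            if lp == 3:
                raise ValueError("the PN has no targets inside the circuit")

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "arrangement": self.arrangement,
            "orn_sources": [asdict(s) for s in self.orn_sources],
            "cells": [asdict(c) for c in self.cells],
            "synapses": [
                {"pre": s.pre, "post": s.post, "params": asdict(s.params)}
                for s in self.synapses
            ],
            "meta": self.meta,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        doc = json.loads(text)
        return cls(
            arrangement=doc["arrangement"],
            orn_sources=[ORNSource(**s) for s in doc["orn_sources"]],
            cells=[Cell(**c) for c in doc["cells"]],
            synapses=[
                Synapse(s["pre"], s["post"], SynapseParams(**s["params"]))
                for s in doc["synapses"]
            ],
            meta=doc.get("meta", {}),
        )


def _syn_params(g: float, e_rev: float, alpha: float, beta: float,
                t_release: float, compound: bool = False) -> SynapseParams:
    return SynapseParams(alpha=alpha, beta=beta, t_release=t_release,
                         g=g, e_rev=e_rev, compound=compound)


def build_elementary(conductances: ConductanceSet, convergence: int = 1000, *,
                     orn_alpha: float = 1 / 20, orn_beta: float = 1 / 50,
                     inter_ln_alpha: float = 1 / 20, inter_ln_beta: float = 1 / 50,
                     output_alpha: float = 1 / 20, output_beta: float = 1 / 50,
                     t_release: float = DEFAULT_T_RELEASE,
                     suffix: str = "") -> NetworkSpec:
    """The elementary ratio-recognition unit: 2 compound ORNs + 5 HH cells, 12 synapses."""
    g = conductances
    s = suffix
    orns = [ORNSource(f"ORNa{s}", "a", convergence), ORNSource(f"ORNb{s}", "b", convergence)]
    cells = [
        Cell(f"LNa{s}", "LN", group="a"),
        Cell(f"LNb{s}", "LN", group="b"),
        Cell(f"LNc{s}", "LN", group="c"),
        Cell(f"LNi{s}", "LNi", i_inj=SPONTANEOUS_CURRENT_NA),
        Cell(f"PN{s}", "PN", i_inj=SPONTANEOUS_CURRENT_NA),
    ]
    exc = dict(e_rev=E_REV_EXC, alpha=orn_alpha, beta=orn_beta,
               t_release=t_release, compound=True)
    inh = dict(e_rev=E_REV_INH, alpha=inter_ln_alpha, beta=inter_ln_beta,
               t_release=t_release)
    out = dict(e_rev=E_REV_INH, alpha=output_alpha, beta=output_beta,
               t_release=t_release)
    synapses = [
        Synapse(f"ORNa{s}", f"LNa{s}", _syn_params(g.g_orn_lnsp, **exc)),
        Synapse(f"ORNb{s}", f"LNb{s}", _syn_params(g.g_orn_lnsp, **exc)),
        Synapse(f"ORNa{s}", f"LNc{s}", _syn_params(g.g_orn_lngen, **exc)),
        Synapse(f"ORNb{s}", f"LNc{s}", _syn_params(g.g_orn_lngen, **exc)),
        # all-to-all directed inter-LN inhibition
        Synapse(f"LNa{s}", f"LNb{s}", _syn_params(g.g_lnt, **inh)),
        Synapse(f"LNb{s}", f"LNa{s}", _syn_params(g.g_lnt, **inh)),
        Synapse(f"LNa{s}", f"LNc{s}", _syn_params(g.g_lni, **inh)),
        Synapse(f"LNb{s}", f"LNc{s}", _syn_params(g.g_lni, **inh)),
        Synapse(f"LNc{s}", f"LNa{s}", _syn_params(g.g_lno, **inh)),
        Synapse(f"LNc{s}", f"LNb{s}", _syn_params(g.g_lno, **inh)),
        # disinhibition pathway (fixed)
        Synapse(f"LNc{s}", f"LNi{s}", _syn_params(g.g_lnc_lni, **out)),
        Synapse(f"LNi{s}", f"PN{s}", _syn_params(g.g_lni_pn, **out)),
    ]
    spec = NetworkSpec("elementary", orns, cells, synapses,
                       meta={"convergence": convergence})
    spec.validate()
    return spec


def build_stacked(n_units: int, conductances: ConductanceSet, convergence: int = 1000,
                  **synapse_kwargs) -> NetworkSpec:
    """Stacked arrangement: independent LN triplets converging on one LNi/PN.

    The elementary triplets keep their internal connectivity and per-LN ORN
    drive; only the LNc→LNi conductance is downscaled by the number of units
    so a unanimous vote reproduces the elementary disinhibition drive.  Each
    unit has its own pair of compound ORN sources so the units' input noise is
    independent.
    """
    if n_units < 1:
        raise ValueError("need at least one unit")
    if n_units == 1:
        return build_elementary(conductances, convergence, **synapse_kwargs)
    g = conductances
    scaled = replace(g, g_lnc_lni=g.g_lnc_lni / n_units)
    orns, cells, synapses = [], [], []
    for u in range(n_units):
        unit = build_elementary(scaled, convergence, suffix=f"_{u}", **synapse_kwargs)
        orns.extend(unit.orn_sources)
        cells.extend(c for c in unit.cells if c.role == "LN")
        synapses.extend(s for s in unit.synapses
                        if not s.pre.startswith("LNi") and not s.post.startswith("LNi"))
        # redirect the unit's LNc→LNi synapse to the shared LNi
        synapses.append(Synapse(f"LNc_{u}", "LNi",
                                next(s.params for s in unit.synapses if s.post == f"LNi_{u}")))
    cells.append(Cell("LNi", "LNi", i_inj=SPONTANEOUS_CURRENT_NA))
    cells.append(Cell("PN", "PN", i_inj=SPONTANEOUS_CURRENT_NA))
    proto = build_elementary(g, convergence, **synapse_kwargs)
    lni_pn = next(s.params for s in proto.synapses if s.post == "PN")
    synapses.append(Synapse("LNi", "PN", lni_pn))
    spec = NetworkSpec("stacked", orns, cells, synapses,
                       meta={"convergence": convergence, "n_units": n_units})
    spec.validate()
    return spec


def build_grouped(n_per_glomerulus: int, conductances: ConductanceSet,
                  convergence: int = 1000, *, within_group_inhibition: bool = False,
                  **synapse_kwargs) -> NetworkSpec:
    """Grouped arrangement: three glomeruli of like LNs with all-to-all
    inhibition between (not within) glomeruli.

    Inter-LN conductances are downscaled by the glomerulus size, conserving
    the total inhibition each LN receives from a rival glomerulus, while every
    LN keeps its full, independent ORN drive (the generalists each receive an
    independent source per component).  Every generalist connects to the
    shared LNi at 1/n of the elementary strength.
    """
    n = n_per_glomerulus
    if n < 1:
        raise ValueError("need at least one LN per glomerulus")
    if n == 1 and not within_group_inhibition:
        return build_elementary(conductances, convergence, **synapse_kwargs)
    g = conductances
    proto = build_elementary(g, convergence, **synapse_kwargs)

    def proto_params(pre: str, post: str) -> SynapseParams:
        return next(s.params for s in proto.synapses if s.pre == pre and s.post == post)

    orns, cells, synapses = [], [], []
    names = {grp: [f"LN{grp}_{k}" for k in range(n)] for grp in "abc"}
    for grp in "abc":
        for k, name in enumerate(names[grp]):
            cells.append(Cell(name, "LN", group=grp))
            comps = ("a",) if grp == "a" else ("b",) if grp == "b" else ("a", "b")
            for comp in comps:
                src = ORNSource(f"ORN{comp}_{name}", comp, convergence)
                orns.append(src)
                gval = g.g_orn_lnsp if grp in "ab" else g.g_orn_lngen
                p = proto_params(f"ORN{comp}", f"LN{comp}" if grp in "ab" else "LNc")
                synapses.append(Synapse(src.name, name, replace(p, g=gval)))
    # inter-glomerular all-to-all inhibition, conductance / n
    pair_g = {("a", "b"): g.g_lnt, ("b", "a"): g.g_lnt,
              ("a", "c"): g.g_lni, ("b", "c"): g.g_lni,
              ("c", "a"): g.g_lno, ("c", "b"): g.g_lno}
    inter_proto = proto_params("LNa", "LNb")
    for (gp, gq), gval in pair_g.items():
        for pre in names[gp]:
            for post in names[gq]:
                synapses.append(Synapse(pre, post, replace(inter_proto, g=gval / n)))
    if within_group_inhibition:
        for grp in "abc":
            for pre in names[grp]:
                for post in names[grp]:
                    if pre != post:
                        gval = g.g_lnt if grp in "ab" else g.g_lni
                        synapses.append(Synapse(pre, post, replace(inter_proto, g=gval / n)))
    cells.append(Cell("LNi", "LNi", i_inj=SPONTANEOUS_CURRENT_NA))
    cells.append(Cell("PN", "PN", i_inj=SPONTANEOUS_CURRENT_NA))
    lnc_lni = proto_params("LNc", "LNi")
    for name in names["c"]:
        synapses.append(Synapse(name, "LNi", replace(lnc_lni, g=g.g_lnc_lni / n)))
    synapses.append(Synapse("LNi", "PN", proto_params("LNi", "PN")))
    spec = NetworkSpec("grouped", orns, cells, synapses,
                       meta={"convergence": convergence, "n_per_glomerulus": n,
                             "within_group_inhibition": within_group_inhibition})
    spec.validate()
    return spec
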