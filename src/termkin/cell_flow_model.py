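"""Steady-state model of intracellular translation termination flows.

The model embeds termination in the full ribosome cycle of a growing
bacterial cell.  Ribosomes are split into three codon classes by the stop
codon of the mRNA they translate (UAA read by RF1 and RF2, UGA by RF2, UAG
by RF1), with fixed subpopulation sizes ``f_X * ribosome_total``.  Each
class cycles through lumped elongation and initiation/recycling stages and
a resolved termination pathway; the classes are coupled only through the
shared pools of free RF1, RF2 and RF3 (the latter speciated as GDP-bound,
nucleotide-free, and GTP-bound).

Class-I RF release from the post-termination complex R_P.RF_i proceeds via
three pathways:

A.  RF3.GDP binds, the ribosome catalyses GDP release, GTP binds the
    ribosome-bound apo-RF3, rotation, class-I RF release, then GTP
    hydrolysis and RF3.GDP departure.
B.  as A, but the RF3.GTP was formed by spontaneous nucleotide exchange in
    solution (pathway D: GDP off-rate ``q_S_3D``) and binds directly.
C.  spontaneous class-I RF release without RF3.

Free GDP is held at zero (the limit that maximises pathway B) so apo-RF3 in
solution can only bind GTP.  Because RF3.GTP that escapes a ribosome by
sampling dissociation re-binds directly, A-vs-B attribution follows a
linear "where was the GTP loaded" tracer on the steady state rather than
the binding channel alone.

The steady state is found by damped fixed-point iteration on the free
factor concentrations (the only nonlinear couplings), with an inner linear
solve per codon class; time integration of the same mass-action system
(:func:`relax_to_steady_state`) is retained as an independent oracle.

Average cycle time and doubling time follow the growth relations: the
population doubling time is proportional to the ribosome-averaged cycle
time tau_R = 1 / sum_X (f_X / tau_R^X).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import RF3Kinetics, SchemeRates, load_rf3_kinetics, load_scheme_rates

__all__ = [
    "CellParams",
    "FlowNetwork",
    "FlowSolution",
    "SteadyStateError",
    "build_network",
    "solve_steady_state",
    "relax_to_steady_state",
    "compute_times",
    "average_cycle_time",
    "titrate",
    "pathway_flux_fractions",
    "supply_demand_analysis",
]

CODONS = ("UAA", "UGA", "UAG")
READERS = {"UAA": ("RF1", "RF2"), "UGA": ("RF2",), "UAG": ("RF1",)}
FREE = ("RF1", "RF2", "RF3_GDP", "RF3_apo", "RF3_GTP")


class SteadyStateError(RuntimeError):
    """Raised when the fixed-point solver cannot reach a balanced state."""


@dataclass(frozen=True)
class CellParams:
    """Whole-cell model inputs.  Concentrations uM, times s, rates s^-1.

    Defaults are the physiological operating point: 20 uM ribosomes
    elongating at 20 codons/s over 300-codon proteins, 1.8 uM total class-I
    RF at an RF2:RF1 ratio of 7, 1 uM total RF3, 0.5 mM free GTP and zero
    free GDP, stop-codon usage 64/27/9 % (UAA/UGA/UAG).  Stage rates not
    measured in vivo (peptide release, subunit splitting, the lumped
    initiation+recycling time, and the post-rotation RF1 clearance, for
    which the 30 C estimate is the closest to growth temperature) are
    reconstruction choices calibrated once against the reference operating
    point: average cycle time ~17 s with RF3 and ~18 s without at ~2 uM
    class-I RF, with sub-second RF2 waiting times.
    """

    ribosome_total: float = 20.0          # uM
    v_R: float = 20.0                     # codons/s per elongating ribosome
    protein_length: float = 300.0         # codons
    stop_fractions: dict[str, float] = field(
        default_factory=lambda: {"UAA": 0.64, "UGA": 0.27, "UAG": 0.09})
    F_tot: float = 1.8                    # uM total class-I RF
    rf2_rf1_ratio: float = 7.0
    F_tot3: float = 1.0                   # uM total RF3
    GTP_mM: float = 0.5
    GDP_mM: float = 0.0                   # held at zero (maximises pathway B)
    q_S_3D: float = 0.03                  # s^-1, GDP off free RF3 in solution
    k_ion: dict[str, float] = field(
        default_factory=lambda: {"RF1": 21.0, "RF2": 10.5})   # uM^-1 s^-1
    k_release: float = 10.0               # s^-1, peptidyl-tRNA hydrolysis
    k_C: dict[str, float] = field(
        default_factory=lambda: {"RF1": 0.1, "RF2": 1.0})     # s^-1, pathway C
    k_3on: float = 2.3                    # uM^-1 s^-1
    k_3off_GDP: float = 1.2156            # s^-1, effective sampling off-rate
    k_3off_GTP: float = 0.5132            # s^-1
    k_rot: float = 3.2                    # s^-1, RF3-bound rotation (k_3BR)
    k_RD_plus: dict[str, float] = field(
        default_factory=lambda: {"RF1": 2.5, "RF2": 3.5})     # s^-1
    k_31D: float = 4.0                    # s^-1, post-class-I RF3 departure
    k_exchange_rib: float = 50.0          # s^-1, on-ribosome GDP release
    k_GTP_on: float = 0.1                 # uM^-1 s^-1, GTP binding to apo-RF3
    tau_IR: float = 0.3                   # s, lumped initiation + recycling
    k_split: float = 10.0                 # s^-1, R_P -> subunit splitting
    ribosomal_exchange: bool = True       # pathway A switch
    solution_exchange: bool = True        # pathway D (hence B) switch
    rf3_present: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.stop_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("stop-codon fractions must sum to 1")
        if set(self.stop_fractions) != set(CODONS):
            raise ValueError(f"stop_fractions must cover {CODONS}")
        for name in ("ribosome_total", "v_R", "protein_length", "rf2_rf1_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("F_tot", "F_tot3", "GTP_mM", "GDP_mM", "q_S_3D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def tau_E(self) -> float:
        """Mean elongation time per protein (s)."""
        return self.protein_length / self.v_R

    @property
    def rf_totals(self) -> dict[str, float]:
        rf1 = self.F_tot / (1.0 + self.rf2_rf1_ratio)
        return {"RF1": rf1, "RF2": self.F_tot - rf1}

    @property
    def k_GTP_eff(self) -> float:
        """Pseudo-first-order GTP binding rate to apo-RF3 (s^-1)."""
        return self.k_GTP_on * self.GTP_mM * 1e3

    @classmethod
    def from_measured(cls, rates1: Optional[SchemeRates] = None,
                      rates2: Optional[SchemeRates] = None,
                      rf3k: Optional[RF3Kinetics] = None,
                      **overrides) -> "CellParams":
        """Build params from measured parameter sets (fixtures by default)."""
        rates1 = rates1 or load_scheme_rates("RF1", 20)
        rates2 = rates2 or load_scheme_rates("RF2", 20)
        rf3k = rf3k or load_rf3_kinetics("GTP")
        gdp = load_rf3_kinetics("GDP")
        kw = dict(
            k_ion={"RF1": rates1.k_ion, "RF2": rates2.k_ion},
            k_RD_plus={"RF1": rates1.k_iRD_plus, "RF2": rates2.k_iRD_plus},
            k_3on=rf3k.k_3on,
            k_3off_GTP=1.0 / rf3k.mean_sampling_dwell,
            k_3off_GDP=1.0 / gdp.mean_sampling_dwell,
            k_rot=rf3k.k_3BR, k_31D=rf3k.k_31D,
        )
        kw.update(overrides)
        return cls(**kw)


# per-class species layout: shared states, then one block per reader
_SHARED = ("R_E", "R_I", "R_A", "R_P", "R_PR3")
_CHAIN = ("RA_F", "RP_F", "RP_F3D", "RP_F3N", "RP_F3T", "RPR_F3")


@dataclass
class FlowNetwork:
    """Mass-action reaction network of the cell model.

    Holds the per-class species index maps and reaction lists.  Reactions
    are (source species, target species, rate constant, free-pool modifier):
    first order in the source, optionally multiplied by one free factor
    concentration.  Factor binding/release bookkeeping lives in
    ``releases``/``binds`` so conservation pools balance identically.
    """

    params: CellParams
    species: dict[str, list[str]] = field(default_factory=dict)
    reactions: dict[str, list[tuple[str, str, float, Optional[str]]]] = \
        field(default_factory=dict)
    # reaction tag -> released free species (for free-pool balance)
    releases: dict[str, list[tuple[str, str, float, str]]] = \
        field(default_factory=dict)

    def class_total(self, codon: str) -> float:
        return self.params.stop_fractions[codon] * self.params.ribosome_total

    def manifest(self) -> dict:
        """Species/reaction inventory (golden-file checked)."""
        return {
            "n_species": sum(len(v) for v in self.species.values()) + len(FREE),
            "n_reactions": sum(len(v) for v in self.reactions.values())
                           + 2,  # solution-phase exchange: GDP->apo, apo->GTP
            "species": {c: list(v) for c, v in self.species.items()},
            "free": list(FREE),
        }

    def rate_matrix(self, codon: str, free: dict[str, float]) -> np.ndarray:
        """Linear generator A with dx/dt = A x for one codon class at fixed
        free-factor concentrations."""
        names = self.species[codon]
        idx = {n: i for i, n in enumerate(names)}
        A = np.zeros((len(names), len(names)))
        for src, dst, k, mod in self.reactions[codon]:
            rate = k * (free[mod] if mod else 1.0)
            A[idx[src], idx[src]] -= rate
            A[idx[dst], idx[src]] += rate
        return A


def build_network(params: CellParams) -> FlowNetwork:
    """Assemble the reaction network for the given parameters.

    Raises ``ValueError`` naming the offending reaction if a required rate
    is missing or negative.
    """
    net = FlowNetwork(params=params)
    p = params
    for name, value in (("k_release", p.k_release), ("k_split", p.k_split),
                        ("k_rot", p.k_rot), ("k_31D", p.k_31D)):
        if value is None or value <= 0:
            raise ValueError(f"reaction rate {name} must be positive, got {value}")
    k_IR = 1.0 / p.tau_IR
    k_E = 1.0 / p.tau_E
    for codon in CODONS:
        names = list(_SHARED)
        rxns: list[tuple[str, str, float, Optional[str]]] = [
            ("R_E", "R_A", k_E, None),
            ("R_I", "R_E", k_IR, None),
            ("R_P", "R_I", p.k_split, None),
            ("R_PR3", "R_P", p.k_31D, None),
        ]
        rel: list[tuple[str, str, float, str]] = [
            ("R_PR3", "R_P", p.k_31D, "RF3_GDP"),
        ]
        for rf in READERS[codon]:
            sp = {s: f"{s}_{rf}" for s in _CHAIN}
            names.extend(sp[s] for s in _CHAIN)
            if p.k_ion[rf] <= 0 or p.k_C[rf] <= 0 or p.k_RD_plus[rf] <= 0:
                raise ValueError(f"rates for {rf} must be positive")
            rxns += [
                ("R_A", sp["RA_F"], p.k_ion[rf], rf),
                (sp["RA_F"], sp["RP_F"], p.k_release, None),
                (sp["RP_F"], "R_P", p.k_C[rf], None),              # pathway C
                ("R_P", sp["RP_F"], p.k_ion[rf], rf),              # rebinding
            ]
            rel.append((sp["RP_F"], "R_P", p.k_C[rf], rf))
            # RF3 branch: always present structurally; flux capacity is zero
            # when the free RF3 pools are zero (F_tot3 = 0 or RF3 absent)
            rxns += [
                (sp["RP_F"], sp["RP_F3D"], p.k_3on, "RF3_GDP"),
                (sp["RP_F"], sp["RP_F3T"], p.k_3on, "RF3_GTP"),
                (sp["RP_F3D"], sp["RP_F"], p.k_3off_GDP, None),
                (sp["RP_F3T"], sp["RP_F"], p.k_3off_GTP, None),
                (sp["RP_F3T"], sp["RPR_F3"], p.k_rot, None),
                (sp["RPR_F3"], "R_PR3", p.k_RD_plus[rf], None),
                (sp["RP_F3N"], sp["RP_F3T"], p.k_GTP_eff, None),
            ]
            rel += [
                (sp["RP_F3D"], sp["RP_F"], p.k_3off_GDP, "RF3_GDP"),
                (sp["RP_F3T"], sp["RP_F"], p.k_3off_GTP, "RF3_GTP"),
                (sp["RPR_F3"], "R_PR3", p.k_RD_plus[rf], rf),
            ]
            if p.ribosomal_exchange:
                rxns.append((sp["RP_F3D"], sp["RP_F3N"], p.k_exchange_rib, None))
        net.species[codon] = names
        net.reactions[codon] = rxns
        net.releases[codon] = rel
    return net


def _bound_factors(net: FlowNetwork, x: dict[str, dict[str, float]]
                   ) -> dict[str, float]:
    """Factor amounts bound in ribosome complexes."""
    bound = {"RF1": 0.0, "RF2": 0.0, "RF3": 0.0}
    for codon in CODONS:
        conc = x[codon]
        for rf in READERS[codon]:
            for s in _CHAIN:
                bound[rf] += conc[f"{s}_{rf}"]
            for s in ("RP_F3D", "RP_F3N", "RP_F3T", "RPR_F3"):
                bound["RF3"] += conc[f"{s}_{rf}"]
        bound["RF3"] += conc["R_PR3"]
    return bound


def _solve_class(net: FlowNetwork, codon: str, free: dict[str, float]
                 ) -> dict[str, float]:
    names = net.species[codon]
    A = net.rate_matrix(codon, free)
    M = A.copy()
    M[-1, :] = 1.0  # replace one balance row with the conservation constraint
    b = np.zeros(len(names))
    b[-1] = net.class_total(codon)
    x = np.linalg.solve(M, b)
    # one step of iterative refinement: rate constants span many orders of
    # magnitude and the raw solve can leave O(1e-11) balance residuals
    x += np.linalg.solve(M, b - M @ x)
    x = np.clip(x, 0.0, None)
    s = x.sum()
    if s > 0:
        x *= net.class_total(codon) / s
    return dict(zip(names, x))


def _free_pool_update(net: FlowNetwork, x: dict[str, dict[str, float]]
                      ) -> dict[str, float]:
    """Candidate free-factor concentrations given the ribosome state."""
    p = net.params
    totals = p.rf_totals
    bound = _bound_factors(net, x)
    cand = {
        "RF1": max(totals["RF1"] - bound["RF1"], 0.0),
        "RF2": max(totals["RF2"] - bound["RF2"], 0.0),
    }
    f3_total = p.F_tot3 if p.rf3_present else 0.0
    free3 = max(f3_total - bound["RF3"], 0.0)
    if free3 <= 0:
        cand.update({"RF3_GDP": 0.0, "RF3_apo": 0.0, "RF3_GTP": 0.0})
        return cand
    # flux balance of the three solution pools at the current ribosome state
    S = sum(x[c][f"RP_F_{rf}"] for c in CODONS for rf in READERS[c])
    q = p.q_S_3D if p.solution_exchange else 0.0
    in_gdp = sum(p.k_31D * x[c]["R_PR3"] for c in CODONS)
    in_gtp = 0.0
    for c in CODONS:
        for rf in READERS[c]:
            in_gdp += p.k_3off_GDP * x[c][f"RP_F3D_{rf}"]
            in_gtp += p.k_3off_GTP * x[c][f"RP_F3T_{rf}"]
    sink = p.k_3on * S
    eps = 1e-300
    gdp = in_gdp / max(sink + q, eps)
    apo = q * gdp / max(p.k_GTP_eff, eps)
    gtp = (in_gtp + p.k_GTP_eff * apo) / max(sink, eps)
    total = gdp + apo + gtp
    if total <= 0:
        pools = {"RF3_GDP": free3, "RF3_apo": 0.0, "RF3_GTP": 0.0}
    else:
        scale = free3 / total
        pools = {"RF3_GDP": gdp * scale, "RF3_apo": apo * scale,
                 "RF3_GTP": gtp * scale}
    cand.update(pools)
    return cand


@dataclass
class FlowSolution:
    """Steady state of the cell flow model."""

    network: FlowNetwork
    concentrations: dict[str, dict[str, float]]   # per codon class
    free: dict[str, float]
    residual: float                               # max |dx/dt| / max flux
    iterations: int

    @property
    def params(self) -> CellParams:
        return self.network.params

    def throughput(self, codon: str) -> float:
        """Per-class cycle flux J^X (uM/s), measured at the elongation exit."""
        return self.concentrations[codon]["R_E"] / self.params.tau_E

    def pool_totals(self) -> dict[str, float]:
        """Recomputed conservation pools (ribosomes per class + factors)."""
        out = {f"ribosomes_{c}": sum(self.concentrations[c].values())
               for c in CODONS}
        bound = _bound_factors(self.network, self.concentrations)
        out["RF1"] = bound["RF1"] + self.free["RF1"]
        out["RF2"] = bound["RF2"] + self.free["RF2"]
        out["RF3"] = bound["RF3"] + (self.free["RF3_GDP"] + self.free["RF3_apo"]
                                     + self.free["RF3_GTP"])
        return out


def _full_rhs(net: FlowNetwork, y: np.ndarray, layout) -> np.ndarray:
    """Mass-action RHS over all species incl. free pools (oracle + residual)."""
    p = net.params
    offsets, free_idx = layout
    dy = np.zeros_like(y)
    free = {f: y[free_idx[f]] for f in FREE}
    for codon in CODONS:
        names = net.species[codon]
        off = offsets[codon]
        idx = {n: off + i for i, n in enumerate(names)}
        for src, dst, k, mod in net.reactions[codon]:
            flux = k * y[idx[src]] * (free[mod] if mod else 1.0)
            dy[idx[src]] -= flux
            dy[idx[dst]] += flux
            if mod:  # binding consumes the free factor
                dy[free_idx[mod]] -= flux
        for src, dst, k, released in net.releases[codon]:
            dy[free_idx[released]] += k * y[idx[src]]
    # solution-phase nucleotide cycle on free RF3
    q = p.q_S_3D if p.solution_exchange else 0.0
    ex1 = q * free["RF3_GDP"]
    ex2 = p.k_GTP_eff * free["RF3_apo"]
    dy[free_idx["RF3_GDP"]] -= ex1
    dy[free_idx["RF3_apo"]] += ex1 - ex2
    dy[free_idx["RF3_GTP"]] += ex2
    return dy


def _layout(net: FlowNetwork):
    offsets = {}
    n = 0
    for codon in CODONS:
        offsets[codon] = n
        n += len(net.species[codon])
    free_idx = {f: n + i for i, f in enumerate(FREE)}
    return (offsets, free_idx), n + len(FREE)


def _pack(net: FlowNetwork, x: dict[str, dict[str, float]],
          free: dict[str, float]) -> np.ndarray:
    layout, n = _layout(net)
    offsets, free_idx = layout
    y = np.zeros(n)
    for codon in CODONS:
        for i, name in enumerate(net.species[codon]):
            y[offsets[codon] + i] = x[codon][name]
    for f in FREE:
        y[free_idx[f]] = free[f]
    return y


def _max_flux(net: FlowNetwork, y: np.ndarray, layout) -> float:
    p = net.params
    offsets, free_idx = layout
    free = {f: y[free_idx[f]] for f in FREE}
    mx = 1e-12
    for codon in CODONS:
        off = offsets[codon]
        idx = {n: off + i for i, n in enumerate(net.species[codon])}
        for src, dst, k, mod in net.reactions[codon]:
            mx = max(mx, k * y[idx[src]] * (free[mod] if mod else 1.0))
    return mx


def solve_steady_state(network: FlowNetwork, max_iter: int = 400,
                       tol: float = 1e-13,
                       residual_tol: float = 1e-8) -> FlowSolution:
    """Fixed-point iteration on the free factor concentrations.

    The only nonlinear couplings are through the five free-factor pools, so
    each outer sweep holds all but one pool fixed and root-solves that
    pool's conservation balance (free + bound(free) = total, a monotone
    bracketed scalar equation) with an inner linear solve of the per-class
    ribosome balances; the RF3 speciation (GDP/apo/GTP) follows from
    solution-phase flux balance and is relaxed between sweeps.  The accepted
    state must satisfy max |dx/dt| <= residual_tol * max reaction flux;
    otherwise a :class:`SteadyStateError` reports the residual.
    """
    from scipy.optimize import brentq

    p = network.params
    totals = p.rf_totals
    f3_total = p.F_tot3 if p.rf3_present else 0.0
    free = {"RF1": totals["RF1"], "RF2": totals["RF2"],
            "RF3_GDP": f3_total, "RF3_apo": 0.0, "RF3_GTP": 0.0}
    spec = {"RF3_GDP": 1.0, "RF3_apo": 0.0, "RF3_GTP": 0.0}

    def solve_classes(trial: dict[str, float]) -> dict[str, dict[str, float]]:
        return {c: _solve_class(network, c, trial) for c in CODONS}

    def mismatch_rf(rf: str, v: float) -> float:
        trial = dict(free); trial[rf] = v
        return v + _bound_factors(network, solve_classes(trial))[rf] - totals[rf]

    def mismatch_f3(v: float) -> float:
        trial = dict(free)
        for k in spec:
            trial[k] = v * spec[k]
        return v + _bound_factors(network, solve_classes(trial))["RF3"] - f3_total

    it = 0
    for it in range(max_iter):
        prev = dict(free)
        for rf in ("RF1", "RF2"):
            if totals[rf] <= 0:
                free[rf] = 0.0
                continue
            if mismatch_rf(rf, totals[rf]) <= 0:
                free[rf] = totals[rf]
            else:
                free[rf] = brentq(lambda v: mismatch_rf(rf, v),
                                  0.0, totals[rf], xtol=1e-24, rtol=9e-16)
        if f3_total > 0:
            if mismatch_f3(f3_total) <= 0:
                v3 = f3_total
            else:
                v3 = brentq(mismatch_f3, 0.0, f3_total, xtol=1e-24, rtol=9e-16)
            for k in spec:
                free[k] = v3 * spec[k]
            # refresh the GDP/apo/GTP split from solution-phase flux balance
            cand = _free_pool_update(network, solve_classes(free))
            total3 = cand["RF3_GDP"] + cand["RF3_apo"] + cand["RF3_GTP"]
            if total3 > 0:
                for k in spec:
                    spec[k] = 0.5 * spec[k] + 0.5 * cand[k] / total3
        delta = max(abs(free[f] - prev[f]) / max(free[f], prev[f], 1e-12)
                    for f in FREE)
        if delta < tol:
            break

    x = solve_classes(free)
    final = _free_pool_update(network, x)
    layout, _ = _layout(network)
    y = _pack(network, x, final)
    resid = float(np.max(np.abs(_full_rhs(network, y, layout))))
    rel = resid / _max_flux(network, y, layout)
    if rel > residual_tol:
        raise SteadyStateError(
            f"fixed point not balanced: relative residual {rel:.3e} "
            f"(tolerance {residual_tol:.1e})")
    return FlowSolution(network=network, concentrations=x, free=final,
                        residual=rel, iterations=it + 1)


def relax_to_steady_state(network: FlowNetwork, t_final: float = 1e5,
                          rtol: float = 1e-8, atol: float = 1e-12
                          ) -> FlowSolution:
    """Independent steady state by long-time integration of the ODE system,
    started from all ribosomes in the elongation stage and all factors free
    (RF3 in the GDP form)."""
    p = network.params
    layout, n = _layout(network)
    offsets, free_idx = layout
    y0 = np.zeros(n)
    for codon in CODONS:
        y0[offsets[codon]] = network.class_total(codon)  # R_E is first
    totals = p.rf_totals
    y0[free_idx["RF1"]] = totals["RF1"]
    y0[free_idx["RF2"]] = totals["RF2"]
    y0[free_idx["RF3_GDP"]] = p.F_tot3 if p.rf3_present else 0.0
    sol = solve_ivp(lambda t, y: _full_rhs(network, y, layout),
                    (0.0, t_final), y0, method="BDF", rtol=rtol, atol=atol)
    if not sol.success:
        raise SteadyStateError(f"ODE relaxation failed: {sol.message}")
    y = np.clip(sol.y[:, -1], 0.0, None)
    x = {c: dict(zip(network.species[c],
                     y[offsets[c]: offsets[c] + len(network.species[c])]))
         for c in CODONS}
    free = {f: float(y[free_idx[f]]) for f in FREE}
    resid = float(np.max(np.abs(_full_rhs(network, y, layout))))
    return FlowSolution(network=network, concentrations=x, free=free,
                        residual=resid / _max_flux(network, y, layout),
                        iterations=sol.t.size)


@dataclass(frozen=True)
class TimeSummary:
    """Waiting, termination and cycle times derived from a steady state."""

    tau_W: dict[str, float]       # s, R_A lifetime per codon
    tau_Term: dict[str, float]    # s, R_A..R_P total per codon
    tau_R_codon: dict[str, float] # s, full cycle per codon
    tau_R: float                  # s, ribosome-averaged cycle time
    throughput: dict[str, float]  # uM/s per codon


def average_cycle_time(fractions: dict[str, float],
                       times: dict[str, float]) -> float:
    """Ribosome-averaged cycle time 1 / sum_X f_X / tau_X (s)."""
    return 1.0 / sum(fractions[c] / times[c] for c in fractions)


def doubling_time_ratio(tau_R: float, tau_R_ref: float) -> float:
    """Doubling-time ratio implied by two cycle times (T_d proportional to
    tau_R at fixed ribosome investment)."""
    return tau_R / tau_R_ref


def compute_times(solution: FlowSolution,
                  params: Optional[CellParams] = None) -> TimeSummary:
    """Per-codon waiting/termination/cycle times and the average cycle time.

    Waiting time is the pre-termination complex lifetime [R_A]/J; the
    termination time sums every state from R_A to R_P over the class flux.
    Zero-throughput classes give infinite times.
    """
    params = params or solution.params
    tau_W, tau_T, tau_R_codon, J = {}, {}, {}, {}
    for codon in CODONS:
        conc = solution.concentrations[codon]
        j = solution.throughput(codon)
        J[codon] = j
        if j <= 0:
            tau_W[codon] = tau_T[codon] = tau_R_codon[codon] = math.inf
            continue
        term = conc["R_A"] + conc["R_P"] + conc["R_PR3"]
        for rf in READERS[codon]:
            term += sum(conc[f"{s}_{rf}"] for s in _CHAIN)
        tau_W[codon] = conc["R_A"] / j
        tau_T[codon] = term / j
        tau_R_codon[codon] = sum(conc.values()) / j
    tau_R = average_cycle_time(params.stop_fractions, tau_R_codon) \
        if all(math.isfinite(t) for t in tau_R_codon.values()) else math.inf
    return TimeSummary(tau_W=tau_W, tau_Term=tau_T, tau_R_codon=tau_R_codon,
                       tau_R=tau_R, throughput=J)


@dataclass(frozen=True)
class PathwayFractions:
    """Class-I RF recycling flux shares of pathways A, B and C."""

    overall: dict[str, float]                 # {"A": .., "B": .., "C": ..}
    per_codon: dict[str, dict[str, float]]
    fluxes: dict[str, float]                  # uM/s


def pathway_flux_fractions(solution: FlowSolution) -> PathwayFractions:
    """Attribute class-I RF recycling flux to pathways A, B and C.

    C is the spontaneous-release flux.  RF3-driven rotations split between A
    (nucleotide exchanged on the ribosome) and B (exchanged in solution) by a
    linear tracer: the solution-loaded fraction of the free RF3.GTP pool and
    of each ribosome-bound GTP state solves a fixed point of the inflow
    mixing relations.  Fractions sum to one over {A, B, C}.
    """
    p = solution.params
    conc = solution.concentrations
    free = solution.free
    chains = [(c, rf) for c in CODONS for rf in READERS[c]]

    rot_in_sol = {}   # inflow to each bound-GTP state from solution binding
    rot_in_rib = {}   # inflow via on-ribosome exchange
    for c, rf in chains:
        rot_in_sol[(c, rf)] = p.k_3on * free["RF3_GTP"] * conc[c][f"RP_F_{rf}"]
        rot_in_rib[(c, rf)] = p.k_GTP_eff * conc[c][f"RP_F3N_{rf}"] \
            if p.rf3_present else 0.0

    # tracer fixed point: phi_T(chain) = c_chain * phi_free;
    # phi_free mixes re-released bound GTP with solution-exchanged supply
    q = p.q_S_3D if p.solution_exchange else 0.0
    g = p.k_GTP_eff * free["RF3_apo"] if p.rf3_present else 0.0
    w_re = {ch: p.k_3off_GTP * conc[ch[0]][f"RP_F3T_{ch[1]}"] for ch in chains}
    cmix = {}
    for ch in chains:
        tot = rot_in_sol[ch] + rot_in_rib[ch]
        cmix[ch] = rot_in_sol[ch] / tot if tot > 0 else 0.0
    W = sum(w_re.values()) + g
    denom = W - sum(w_re[ch] * cmix[ch] for ch in chains)
    phi_free = g / denom if denom > 0 else 0.0
    phi_free = min(max(phi_free, 0.0), 1.0)

    flux = {"A": 0.0, "B": 0.0, "C": 0.0}
    per_codon: dict[str, dict[str, float]] = {}
    for c in CODONS:
        fc = {"A": 0.0, "B": 0.0, "C": 0.0}
        for rf in READERS[c]:
            ch = (c, rf)
            rot = p.k_rot * conc[c][f"RP_F3T_{rf}"] if p.rf3_present else 0.0
            phi_T = cmix[ch] * phi_free
            fc["B"] += rot * phi_T
            fc["A"] += rot * (1.0 - phi_T)
            fc["C"] += p.k_C[rf] * conc[c][f"RP_F_{rf}"]
        per_codon[c] = fc
        for k in flux:
            flux[k] += fc[k]

    def _norm(d: dict[str, float]) -> dict[str, float]:
        s = sum(d.values())
        return {k: (v / s if s > 0 else math.nan) for k, v in d.items()}

    return PathwayFractions(overall=_norm(flux),
                            per_codon={c: _norm(f) for c, f in per_codon.items()},
                            fluxes=flux)


@dataclass(frozen=True)
class TitrationPoint:
    value: float
    solution: FlowSolution
    times: TimeSummary
    fractions: PathwayFractions


def titrate(params: CellParams, species: str, grid: Sequence[float],
            **solver_kwargs) -> list[TitrationPoint]:
    """Solve the steady state along a concentration grid.

    ``species`` is ``"F_tot"`` (total class-I RF) or ``"F_tot3"`` (total
    RF3); the grid must be positive and monotone increasing.  Solver errors
    propagate annotated with the offending grid value.
    """
    if species not in ("F_tot", "F_tot3"):
        raise ValueError("species must be 'F_tot' or 'F_tot3'")
    g = np.asarray(grid, dtype=float)
    if g.size == 0 or np.any(g < 0) or (g.size > 1 and np.any(np.diff(g) <= 0)):
        raise ValueError("grid must be positive and strictly increasing")
    out = []
    for value in g:
        pt = replace(params, **{species: float(value)})
        net = build_network(pt)
        try:
            sol = solve_steady_state(net, **solver_kwargs)
        except SteadyStateError as err:
            raise SteadyStateError(f"at {species}={value}: {err}") from err
        out.append(TitrationPoint(value=float(value), solution=sol,
                                  times=compute_times(sol),
                                  fractions=pathway_flux_fractions(sol)))
    return out


def supply_demand_analysis(params: CellParams
                           ) -> tuple[float, float, float]:
    """Demand flow for activated RF3.GTP vs its maximal spontaneous supply.

    Demand: termination events per second, ribosome_total * v_R /
    protein_length (uM/s).  Supply cap: total RF3 times the solution GDP
    off-rate, the infinite [GTP]/[GDP] limit.  Returns (demand, supply cap,
    supply/demand).
    """
    if params.protein_length <= 0:
        raise ValueError("protein_length must be > 0")
    demand = params.ribosome_total * params.v_R / params.protein_length
    supply = params.F_tot3 * params.q_S_3D
    return demand, supply, supply / demand
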