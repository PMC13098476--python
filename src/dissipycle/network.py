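"""Reaction networks for the three dissipative circuit topologies.

Each circuit is encoded as an explicit :class:`ReactionNetwork`: a species
list, an integer stoichiometry matrix, one declarative rate law per reaction
and the conserved moieties implied by the wiring. Three builders assemble
the networks:

* :func:`build_dnazyme_cycle` — fuel-driven activation of a bipartite
  DNAzyme with exonuclease digestion of the fuel duplex,
* :func:`build_trypsin_cycle` — aptamer-gated trypsin with fuel-driven
  release and exonuclease-dissipated aptamer/fuel duplex,
* :func:`build_coupled_network` — the unidirectional relay in which the
  transient DNAzyme cleaves an inhibitor duplex, T7 digestion of the cleaved
  inhibitor releases the trypsin fuel, and Exo III dissipates both cycles.

Rate-law conventions: hybridizations are irreversible mass action (the
duplexes are designed not to dissociate spontaneously); enzymatic steps are
Michaelis–Menten; when one enzyme has several substrates they share a
competitive denominator 1 + Σ_j [S_j]/Km_j. Exonuclease maximal rates are
``c · U · φ(L)`` where U is the enzyme load in U·µL⁻¹, c the fitted unit
conversion and φ the toe-hold attenuation factor. Digestion releases the
protected partner strand intact and produces one unit of lumped waste; when
``K_W`` is finite the waste scales the effective exonuclease rate by
1/(1+[W]/K_W) (fatigue model), and the default ``K_W = ∞`` is the ideal
waste-free model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .params import Condition, KineticParams

__all__ = [
    "MassAction",
    "FirstOrder",
    "MichaelisMenten",
    "Reaction",
    "ReactionNetwork",
    "toehold_rate_factor",
    "build_dnazyme_cycle",
    "build_trypsin_cycle",
    "build_coupled_network",
    "build_network",
]


# --------------------------------------------------------------------------
# rate-law descriptors


@dataclass(frozen=True)
class MassAction:
    """v = k · Π [reactant] (irreversible)."""

    k: float
    reactants: tuple[str, ...]


@dataclass(frozen=True)
class FirstOrder:
    """v = k · [species]."""

    k: float
    species: str


@dataclass(frozen=True)
class MichaelisMenten:
    """Michaelis–Menten conversion of ``substrate``, optionally competitive.

    The maximal rate is either ``kcat·[catalyst]`` (a catalytic species such
    as the active DNAzyme duplex or free trypsin) or a fixed ``vmax`` in
    µM·min⁻¹ (an exonuclease whose load is given in activity units, folded
    in at build time). ``efficiency`` is a substrate-specific multiplier on
    the maximal rate (the toe-hold factor φ). Reactions sharing ``group``
    contribute [S]/Km terms to a common competitive denominator. With
    ``waste_inhibited`` the maximal rate is further scaled by
    1/(1+[Waste]/K_W).
    """

    substrate: str
    Km: float
    kcat: float | None = None
    catalyst: str | None = None
    vmax: float | None = None
    efficiency: float = 1.0
    group: str | None = None
    waste_inhibited: bool = False
    K_W: float = math.inf

    def __post_init__(self) -> None:
        if (self.kcat is None) == (self.vmax is None):
            raise ValueError("specify exactly one of kcat/catalyst or vmax")
        if self.kcat is not None and self.catalyst is None:
            raise ValueError("kcat requires a catalyst species")


RateLaw = MassAction | FirstOrder | MichaelisMenten


@dataclass(frozen=True)
class Reaction:
    name: str
    stoich: dict[str, int]
    rate: RateLaw


@dataclass(frozen=True)
class ReactionNetwork:
    """A circuit variant as species, stoichiometry and rate laws."""

    circuit_id: str
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    conserved: tuple[tuple[str, dict[str, int]], ...]

    def __post_init__(self) -> None:
        declared = set(self.species)
        for rxn in self.reactions:
            for sp in rxn.stoich:
                if sp not in declared:
                    raise ValueError(f"reaction {rxn.name} references undeclared species {sp}")
            law = rxn.rate
            refs: tuple[str, ...]
            if isinstance(law, MassAction):
                refs = law.reactants
            elif isinstance(law, FirstOrder):
                refs = (law.species,)
            else:
                refs = (law.substrate,) + ((law.catalyst,) if law.catalyst else ())
            for sp in refs:
                if sp not in declared:
                    raise ValueError(f"rate law of {rxn.name} references undeclared species {sp}")
        for name, vec in self.conserved:
            for sp in vec:
                if sp not in declared:
                    raise ValueError(f"conserved moiety {name} references undeclared species {sp}")

    # -- structure ----------------------------------------------------------

    def index(self, species: str) -> int:
        return self.species.index(species)

    def stoichiometry_matrix(self) -> np.ndarray:
        """Integer stoichiometry matrix N (n_species × n_reactions)."""
        n = np.zeros((len(self.species), len(self.reactions)), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            for sp, coeff in rxn.stoich.items():
                n[self.index(sp), j] = coeff
        return n

    def conserved_vectors(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for name, vec in self.conserved:
            v = np.zeros(len(self.species), dtype=np.int64)
            for sp, coeff in vec.items():
                v[self.index(sp)] = coeff
            out.append((name, v))
        return out

    def initial_state(self, cond: Condition) -> np.ndarray:
        x0 = np.zeros(len(self.species))
        for sp, conc in cond.initial.items():
            if sp in self.species:
                x0[self.index(sp)] = conc
        return x0

    # -- rate evaluation ----------------------------------------------------

    def rate_functions(self) -> list[Callable[[np.ndarray], float]]:
        """One scalar rate closure per reaction; argument is the state in µM.

        Negative concentrations (solver round-off) are floored at zero inside
        the closures; the solution itself is never clipped.
        """
        idx = {sp: i for i, sp in enumerate(self.species)}
        # Precompute competitive groups: group id -> [(substrate index, Km)]
        groups: dict[str, list[tuple[int, float]]] = {}
        for rxn in self.reactions:
            law = rxn.rate
            if isinstance(law, MichaelisMenten) and law.group is not None:
                groups.setdefault(law.group, []).append((idx[law.substrate], law.Km))
        w_i = idx.get("Waste")

        funcs: list[Callable[[np.ndarray], float]] = []
        for rxn in self.reactions:
            law = rxn.rate
            if isinstance(law, MassAction):
                k = law.k
                ris = tuple(idx[sp] for sp in law.reactants)
                if len(ris) == 1:
                    (i0,) = ris
                    funcs.append(lambda x, k=k, i0=i0: k * max(x[i0], 0.0))
                elif len(ris) == 2:
                    i0, i1 = ris
                    funcs.append(
                        lambda x, k=k, i0=i0, i1=i1: k * max(x[i0], 0.0) * max(x[i1], 0.0)
                    )
                else:  # pragma: no cover - no circuit uses ternary steps
                    funcs.append(
                        lambda x, k=k, ris=ris: k * float(np.prod([max(x[i], 0.0) for i in ris]))
                    )
            elif isinstance(law, FirstOrder):
                k, i0 = law.k, idx[law.species]
                funcs.append(lambda x, k=k, i0=i0: k * max(x[i0], 0.0))
            else:
                s_i = idx[law.substrate]
                Km = law.Km
                members = groups.get(law.group) if law.group is not None else [(s_i, Km)]
                cat_i = idx[law.catalyst] if law.catalyst is not None else None
                kcat, vmax, eff = law.kcat, law.vmax, law.efficiency
                winh = law.waste_inhibited and math.isfinite(law.K_W)
                K_W = law.K_W

                def mm_rate(
                    x,
                    s_i=s_i,
                    Km=Km,
                    members=tuple(members),
                    cat_i=cat_i,
                    kcat=kcat,
                    vmax=vmax,
                    eff=eff,
                    winh=winh,
                    K_W=K_W,
                    w_i=w_i,
                ):
                    vm = vmax if vmax is not None else kcat * max(x[cat_i], 0.0)
                    if winh:
                        vm /= 1.0 + max(x[w_i], 0.0) / K_W
                    denom = 1.0
                    for j, kmj in members:
                        denom += max(x[j], 0.0) / kmj
                    return eff * vm * (max(x[s_i], 0.0) / Km) / denom

                funcs.append(mm_rate)
        return funcs

    def rates(self, x: np.ndarray) -> np.ndarray:
        return np.array([f(x) for f in self.rate_functions()])

    def rhs(self) -> Callable[[float, np.ndarray], np.ndarray]:
        """Compiled ODE right-hand side dx/dt = N·v(x)."""
        funcs = self.rate_functions()
        n = self.stoichiometry_matrix().astype(float)

        def f(t: float, x: np.ndarray) -> np.ndarray:
            v = np.array([fn(x) for fn in funcs])
            return n @ v

        return f


# --------------------------------------------------------------------------
# toe-hold digestion kinetics


def toehold_rate_factor(L: int, enzyme: str, params: KineticParams) -> float:
    """Toe-hold attenuation factor φ(L) ∈ (0, 1] for exonuclease initiation.

    Both exonucleases initiate only on duplex ends with short single-strand
    overhangs — Exo III tolerates up to ~4 nt, T7 up to ~12 nt — and longer
    overhangs slow initiation. The default model is the smooth attenuation
    φ(L) = exp(−β·L); with ``params.toehold_cutoff`` the factor is zeroed
    beyond the enzyme's hard overhang limit.
    """
    if not (isinstance(L, (int, np.integer)) and L >= 0):
        raise ValueError("toe-hold length must be a non-negative integer")
    if enzyme == "exoIII":
        beta, lmax = params.beta_exo, params.Lmax_exo
    elif enzyme == "t7":
        beta, lmax = params.beta_t7, params.Lmax_t7
    else:
        raise ValueError(f"unknown enzyme {enzyme!r}")
    phi = math.exp(-beta * L)
    if params.toehold_cutoff and L > lmax:
        return 0.0
    return phi


def _digesting_enzyme(circuit_id: str) -> str:
    return "t7" if circuit_id.endswith("_t7") else "exoIII"


def _enzyme_vmax(enzyme: str, params: KineticParams, cond: Condition) -> tuple[float, float]:
    """(Vmax in µM/min, Km in µM) for an exonuclease at this condition."""
    if enzyme == "exoIII":
        u = cond.enzymes.get("exoIII", 0.0)
        return params.c_exo * u, params.Km_exo
    u = cond.enzymes.get("t7", 0.0)
    return params.c_t7 * u, params.Km_t7


# --------------------------------------------------------------------------
# circuit builders


def build_dnazyme_cycle(params: KineticParams, cond: Condition) -> ReactionNetwork:
    """Assemble the exonuclease-dissipated DNAzyme cycle.

    Species: protected DNAzyme strand ``S1``, DNAzyme fuel ``Fuel``, active
    duplex ``Dz``, reporter ``Rep`` / ``RepCleaved``, lumped digestion
    ``Waste``. Fuel addition forms the active duplex (mass action), the
    duplex cleaves the reporter (MM), and the exonuclease digests the duplex
    releasing the protected strand intact (MM with toe-hold factor).
    """
    if cond.circuit_id not in ("dnazyme_exoIII", "dnazyme_t7"):
        raise ValueError(f"circuit_id {cond.circuit_id!r} is not a DNAzyme cycle")
    if not cond.ref_conc_uM > 0:
        raise ValueError("non-positive reference concentration")
    enzyme = _digesting_enzyme(cond.circuit_id)
    vmax, km_dig = _enzyme_vmax(enzyme, params, cond)
    phi = toehold_rate_factor(cond.L_fuel, enzyme, params)

    reactions = (
        Reaction(
            "hybridization",
            {"S1": -1, "Fuel": -1, "Dz": +1},
            MassAction(params.k_hyb_dz, ("S1", "Fuel")),
        ),
        Reaction(
            "reporter_cleavage",
            {"Rep": -1, "RepCleaved": +1},
            MichaelisMenten(
                substrate="Rep", Km=params.Km_rep, kcat=params.k_cat_rep,
                catalyst="Dz", group="dz",
            ),
        ),
        Reaction(
            "fuel_digestion",
            {"Dz": -1, "S1": +1, "Waste": +1},
            MichaelisMenten(
                substrate="Dz", Km=km_dig, vmax=vmax, efficiency=phi,
                group=enzyme, waste_inhibited=True, K_W=params.K_W,
            ),
        ),
    )
    conserved = (
        ("dnazyme_strand", {"S1": 1, "Dz": 1}),
        ("reporter", {"Rep": 1, "RepCleaved": 1}),
        ("fuel", {"Fuel": 1, "Dz": 1, "Waste": 1}),
    )
    return ReactionNetwork(
        circuit_id=cond.circuit_id,
        species=("S1", "Fuel", "Dz", "Rep", "RepCleaved", "Waste"),
        reactions=reactions,
        conserved=conserved,
    )


def _trypsin_reactions(params: KineticParams, vmax: float, km_dig: float,
                       phi: float, enzyme: str) -> list[Reaction]:
    rxns = [
        Reaction(
            "trypsin_release",
            {"TryApt": -1, "Try": +1, "Apt": +1},
            FirstOrder(params.k_off_TA, "TryApt"),
        ),
        Reaction(
            "trypsin_inhibition",
            {"Try": -1, "Apt": -1, "TryApt": +1},
            MassAction(params.k_on_TA, ("Try", "Apt")),
        ),
        Reaction(
            "aptamer_fuel_hybridization",
            {"Apt": -1, "FuelTry": -1, "AptFuel": +1},
            MassAction(params.k_hyb_apt, ("Apt", "FuelTry")),
        ),
    ]
    if params.k_disp > 0:
        rxns.append(
            Reaction(
                "fuel_displacement",
                {"TryApt": -1, "FuelTry": -1, "Try": +1, "AptFuel": +1},
                MassAction(params.k_disp, ("TryApt", "FuelTry")),
            )
        )
    rxns.append(
        Reaction(
            "bapna_cleavage",
            {"LBAPNA": -1, "pNA": +1},
            MichaelisMenten(
                substrate="LBAPNA", Km=params.Km_try, kcat=params.k_cat_try,
                catalyst="Try",
            ),
        )
    )
    rxns.append(
        Reaction(
            "tryfuel_digestion",
            {"AptFuel": -1, "Apt": +1, "Waste": +1},
            MichaelisMenten(
                substrate="AptFuel", Km=km_dig, vmax=vmax, efficiency=phi,
                group=enzyme, waste_inhibited=True, K_W=params.K_W,
            ),
        )
    )
    return rxns


def build_trypsin_cycle(params: KineticParams, cond: Condition) -> ReactionNetwork:
    """Assemble the aptamer-gated, exonuclease-dissipated trypsin cycle.

    Trypsin starts sequestered by a ssDNA aptamer (``TryApt``); the trypsin
    fuel hybridizes free aptamer into the digestible ``AptFuel`` duplex,
    pulling the binding equilibrium open so free trypsin cleaves L-BAPNA to
    p-nitroaniline. Exonuclease digestion of ``AptFuel`` recycles the intact
    aptamer, which re-binds and silences trypsin.
    """
    if cond.circuit_id not in ("trypsin_exoIII", "trypsin_t7"):
        raise ValueError(f"circuit_id {cond.circuit_id!r} is not a trypsin cycle")
    if not cond.ref_conc_uM > 0:
        raise ValueError("non-positive reference concentration")
    enzyme = _digesting_enzyme(cond.circuit_id)
    vmax, km_dig = _enzyme_vmax(enzyme, params, cond)
    phi = toehold_rate_factor(cond.L_tryfuel, enzyme, params)

    rxns = _trypsin_reactions(params, vmax, km_dig, phi, enzyme)
    conserved = (
        ("trypsin", {"Try": 1, "TryApt": 1}),
        ("aptamer", {"Apt": 1, "TryApt": 1, "AptFuel": 1}),
        ("substrate", {"LBAPNA": 1, "pNA": 1}),
        ("tryfuel", {"FuelTry": 1, "AptFuel": 1, "Waste": 1}),
    )
    return ReactionNetwork(
        circuit_id=cond.circuit_id,
        species=("TryApt", "Try", "Apt", "FuelTry", "AptFuel", "LBAPNA", "pNA", "Waste"),
        reactions=tuple(rxns),
        conserved=conserved,
    )


def build_coupled_network(params: KineticParams, cond: Condition) -> ReactionNetwork:
    """Assemble the unidirectionally communicating coupled network.

    The DNAzyme cycle runs as above, but the active duplex has a second,
    competing substrate: the inhibitor duplex that sequesters the trypsin
    fuel. DNAzyme cleavage strips the inhibitor's protected end, T7 digests
    the cleaved inhibitor and releases the trypsin fuel, and Exo III
    dissipates both the DNAzyme fuel duplex and the aptamer/fuel duplex
    through one shared competitive denominator. The intact inhibitor duplex
    is protected at both ends and is not a T7 substrate.
    """
    if cond.circuit_id != "coupled":
        raise ValueError(f"circuit_id {cond.circuit_id!r} is not the coupled network")
    for enz in ("exoIII", "t7"):
        if enz not in cond.enzymes:
            raise ValueError(f"coupled network requires an explicit {enz} load")
    vmax_exo, km_exo = _enzyme_vmax("exoIII", params, cond)
    vmax_t7, km_t7 = _enzyme_vmax("t7", params, cond)
    phi_fuel = toehold_rate_factor(cond.L_fuel, "exoIII", params)
    phi_tryfuel = toehold_rate_factor(cond.L_tryfuel, "exoIII", params)

    rxns = [
        Reaction(
            "hybridization",
            {"S1": -1, "Fuel": -1, "Dz": +1},
            MassAction(params.k_hyb_dz, ("S1", "Fuel")),
        ),
        Reaction(
            "reporter_cleavage",
            {"Rep": -1, "RepCleaved": +1},
            MichaelisMenten(
                substrate="Rep", Km=params.Km_rep, kcat=params.k_cat_rep,
                catalyst="Dz", group="dz",
            ),
        ),
        Reaction(
            "inhibitor_cleavage",
            {"InhibDuplex": -1, "InhibDuplexCleaved": +1},
            MichaelisMenten(
                substrate="InhibDuplex", Km=params.Km_inh, kcat=params.k_cat_inh,
                catalyst="Dz", group="dz",
            ),
        ),
        Reaction(
            "fuel_digestion",
            {"Dz": -1, "S1": +1, "Waste": +1},
            MichaelisMenten(
                substrate="Dz", Km=km_exo, vmax=vmax_exo, efficiency=phi_fuel,
                group="exoIII", waste_inhibited=True, K_W=params.K_W,
            ),
        ),
        Reaction(
            "inhibitor_digestion",
            {"InhibDuplexCleaved": -1, "FuelTry": +1, "Waste": +1},
            MichaelisMenten(
                substrate="InhibDuplexCleaved", Km=km_t7, vmax=vmax_t7,
                group="t7", waste_inhibited=True, K_W=params.K_W,
            ),
        ),
    ]
    rxns += _trypsin_reactions(params, vmax_exo, km_exo, phi_tryfuel, "exoIII")
    conserved = (
        ("dnazyme_strand", {"S1": 1, "Dz": 1}),
        ("reporter", {"Rep": 1, "RepCleaved": 1}),
        ("trypsin", {"Try": 1, "TryApt": 1}),
        ("aptamer", {"Apt": 1, "TryApt": 1, "AptFuel": 1}),
        ("substrate", {"LBAPNA": 1, "pNA": 1}),
    )
    return ReactionNetwork(
        circuit_id="coupled",
        species=(
            "S1", "Fuel", "Dz", "Rep", "RepCleaved",
            "InhibDuplex", "InhibDuplexCleaved",
            "TryApt", "Try", "Apt", "FuelTry", "AptFuel",
            "LBAPNA", "pNA", "Waste",
        ),
        reactions=tuple(rxns),
        conserved=conserved,
    )


_BUILDERS = {
    "dnazyme_exoIII": build_dnazyme_cycle,
    "dnazyme_t7": build_dnazyme_cycle,
    "trypsin_exoIII": build_trypsin_cycle,
    "trypsin_t7": build_trypsin_cycle,
    "coupled": build_coupled_network,
}


def build_network(params: KineticParams, cond: Condition) -> ReactionNetwork:
    """Dispatch to the builder matching ``cond.circuit_id``."""
    return _BUILDERS[cond.circuit_id](params, cond)
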