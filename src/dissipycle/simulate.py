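"""Forward simulation of circuit networks with impulsive fuel dosing.

:func:`integrate` solves the deterministic mass-action/Michaelis–Menten
ODEs with a stiff-capable solver, restarting at every dose event (an
instantaneous concentration jump, optionally with a dilution factor).
:func:`observables` maps species trajectories to the optical channels the
plate reader records (520 nm fluorescence of the cleaved reporter, 405 nm
absorbance of p-nitroaniline). :func:`ssa_simulate` is an exact stochastic
simulation of the same network used as an independent oracle for the
deterministic solution; Michaelis–Menten laws enter as mean-field
propensities (deterministic rate × volume), a documented approximation —
the deterministic model is the object under test.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import MassAction, FirstOrder, MichaelisMenten, ReactionNetwork

__all__ = [
    "DoseEvent",
    "Trace",
    "SignalTrace",
    "SimulationError",
    "integrate",
    "observables",
    "ssa_simulate",
    "write_signals_csv",
    "read_signals_csv",
]

CHANNEL_SPECIES = {"fluor520": "RepCleaved", "abs405": "pNA"}


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails on a segment."""


@dataclass(frozen=True)
class DoseEvent:
    """An impulsive addition of one species at a given time.

    ``amount`` is in µM added to the named species; ``dilution`` scales all
    concentrations at the dose time (1 = the spike volume is negligible).
    """

    time: float
    species: str = "Fuel"
    amount: float = 0.0
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be non-negative")
        if self.amount < 0:
            raise ValueError("dose amount must be non-negative")
        if not (0.0 < self.dilution <= 1.0):
            raise ValueError("dilution must be in (0, 1]")


@dataclass(frozen=True)
class Trace:
    """Species trajectories on a regular output grid (µM vs minutes)."""

    time: np.ndarray
    states: np.ndarray  # (n_species, n_time)
    species: tuple[str, ...]
    dose_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.states.shape != (len(self.species), len(self.time)):
            raise ValueError("states must be (n_species, n_time)")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def species_series(self, name: str) -> np.ndarray:
        return self.states[self.species.index(name)]

    def conservation_residual(self, network: ReactionNetwork) -> float:
        """Worst relative drift of any conserved moiety between dose events.

        Doses legitimately change moiety totals, so each inter-dose segment
        is referenced to its own first sample.
        """
        edges = [t for t in self.dose_times if self.time[0] < t < self.time[-1]]
        bounds = [self.time[0], *edges, self.time[-1] + 1.0]
        worst = 0.0
        for name, v in network.conserved_vectors():
            totals = v @ self.states
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                # dose-time samples hold the pre-dose state: include the left
                # edge in the segment that ends there, not the one it starts.
                seg = totals[(self.time > lo) & (self.time <= hi)] if lo in edges \
                    else totals[(self.time >= lo) & (self.time <= hi)]
                if seg.size == 0:
                    continue
                ref = seg[0]
                scale = abs(ref) if ref != 0 else 1.0
                worst = max(worst, float(np.max(np.abs(seg - ref)) / scale))
        return worst


@dataclass(frozen=True)
class SignalTrace:
    """One optical channel sampled on the trace's time grid."""

    channel: str
    time: np.ndarray
    values: np.ndarray
    normalization: str = "raw"
    condition_id: str = ""

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_SPECIES:
            raise ValueError(f"unknown channel {self.channel!r}")
        if len(self.time) != len(self.values):
            raise ValueError("time and values must have equal length")
        if self.normalization not in ("raw", "delta", "minmax"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def replace(self, **changes) -> "SignalTrace":
        return replace(self, **changes)


# --------------------------------------------------------------------------
# deterministic integration


def integrate(
    network: ReactionNetwork,
    init: np.ndarray | dict[str, float],
    schedule: Sequence[DoseEvent] = (),
    t_end: float = 100.0,
    dt_out: float = 0.5,
    t0: float = 0.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trace:
    """Integrate the network ODEs over ``[t0, t_end]`` with dose events.

    The state is sampled on the uniform grid ``t0 + k·dt_out``. At each dose
    time the state jumps (species += amount, then all species ×= dilution)
    and integration restarts; a grid point that coincides with a dose time
    reports the pre-dose state, so per-cycle baselines are well defined.
    """
    if dt_out <= 0:
        raise ValueError("dt_out must be positive")
    if isinstance(init, dict):
        x = np.zeros(len(network.species))
        for sp, conc in init.items():
            x[network.index(sp)] = conc
    else:
        x = np.asarray(init, dtype=float).copy()
    if x.shape != (len(network.species),):
        raise ValueError("init has wrong length")
    if np.any(x < 0):
        raise ValueError("negative initial concentrations")
    times = [e.time for e in schedule]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("schedule must be sorted by time without duplicates")
    if any(t < t0 or t > t_end for t in times):
        raise ValueError("dose times must lie within [t0, t_end]")

    n_out = int(round((t_end - t0) / dt_out))
    grid = t0 + dt_out * np.arange(n_out + 1)
    out = np.empty((len(network.species), grid.size))
    rhs = network.rhs()

    seg_edges = [t0, *times, t_end]
    filled = 0
    for k, (lo, hi) in enumerate(zip(seg_edges[:-1], seg_edges[1:])):
        if k > 0:
            ev = schedule[k - 1]
            if ev.species not in network.species:
                raise ValueError(f"dose species {ev.species!r} not in network")
            x[network.index(ev.species)] += ev.amount
            x *= ev.dilution
        # grid points inside (lo, hi]; the point at lo (if any) was already
        # written by the previous segment with the pre-dose state.
        mask = (grid > lo) & (grid <= hi) if k > 0 else (grid >= lo) & (grid <= hi)
        t_eval = grid[mask]
        if hi > lo:
            # always integrate up to hi so the next segment starts there
            t_solver = t_eval if t_eval.size and t_eval[-1] == hi \
                else np.append(t_eval, hi)
            sol = solve_ivp(
                rhs, (lo, hi), x, method=method, t_eval=t_solver,
                rtol=rtol, atol=atol, dense_output=False,
            )
            if not sol.success:
                raise SimulationError(
                    f"solver failed on segment [{lo}, {hi}] "
                    f"(state={x.tolist()}): {sol.message}"
                )
            if t_eval.size:
                out[:, mask] = sol.y[:, : t_eval.size]
                filled += t_eval.size
            x = sol.y[:, -1].copy()
        elif t_eval.size:
            out[:, mask] = x[:, None]
            filled += t_eval.size
    assert filled == grid.size
    return Trace(time=grid, states=out, species=network.species,
                 dose_times=tuple(times))


def observables(
    trace: Trace,
    params,
    channel: str = "fluor520",
    normalization: str = "raw",
    condition_id: str = "",
) -> SignalTrace:
    """Map a species trajectory to an optical channel.

    ``fluor520`` is F0 + alpha_F·[RepCleaved]; ``abs405`` is
    A0 + eps_A·[pNA]. ``delta`` subtracts the value at the first dose time
    (or the first sample if the trace has no doses); ``minmax`` rescales the
    trace to [0, 1].
    """
    try:
        species = CHANNEL_SPECIES[channel]
    except KeyError:
        raise ValueError(f"unknown channel {channel!r}") from None
    if species not in trace.species:
        raise ValueError(f"channel {channel} requires species {species} in the trace")
    conc = trace.species_series(species)
    if channel == "fluor520":
        values = params.F0 + params.alpha_F * conc
    else:
        values = params.A0 + params.eps_A * conc
    if normalization == "delta":
        t_ref = trace.dose_times[0] if trace.dose_times else trace.time[0]
        values = values - np.interp(t_ref, trace.time, values)
    elif normalization == "minmax":
        lo, hi = float(values.min()), float(values.max())
        values = (values - lo) / (hi - lo) if hi > lo else np.zeros_like(values)
    return SignalTrace(channel=channel, time=trace.time.copy(), values=values,
                       normalization=normalization, condition_id=condition_id)


# --------------------------------------------------------------------------
# stochastic oracle


def _compile_propensities(network: ReactionNetwork, volume_scale: float):
    """Per-reaction propensity closures over a plain list of copy numbers."""
    idx = {sp: i for i, sp in enumerate(network.species)}
    groups: dict[str, list[tuple[int, float]]] = {}
    for rxn in network.reactions:
        law = rxn.rate
        if isinstance(law, MichaelisMenten) and law.group is not None:
            groups.setdefault(law.group, []).append((idx[law.substrate], law.Km))
    w_i = idx.get("Waste")
    v = volume_scale

    props = []
    changes = []
    for rxn in network.reactions:
        law = rxn.rate
        if isinstance(law, MassAction):
            ris = tuple(idx[sp] for sp in law.reactants)
            if len(ris) == 1:
                (i0,) = ris
                props.append(lambda n, k=law.k, i0=i0: k * n[i0])
            else:
                i0, i1 = ris
                # conc-based bimolecular rate scaled to counts: k·n_i·n_j/V
                props.append(lambda n, k=law.k, i0=i0, i1=i1: k * n[i0] * n[i1] / v)
        elif isinstance(law, FirstOrder):
            i0 = idx[law.species]
            props.append(lambda n, k=law.k, i0=i0: k * n[i0])
        else:
            s_i = idx[law.substrate]
            members = tuple(groups.get(law.group) or [(s_i, law.Km)])
            cat_i = idx[law.catalyst] if law.catalyst is not None else None
            winh = law.waste_inhibited and math.isfinite(law.K_W)

            def prop(n, s_i=s_i, Km=law.Km, members=members, cat_i=cat_i,
                     kcat=law.kcat, vmax=law.vmax, eff=law.efficiency,
                     winh=winh, K_W=law.K_W, w_i=w_i, v=v):
                vm = vmax * v if vmax is not None else kcat * n[cat_i]
                if winh:
                    vm /= 1.0 + n[w_i] / (K_W * v)
                denom = 1.0
                for j, kmj in members:
                    denom += n[j] / (kmj * v)
                return eff * vm * (n[s_i] / (Km * v)) / denom

            props.append(prop)
        changes.append([(idx[sp], d) for sp, d in rxn.stoich.items()])
    return props, changes


def ssa_simulate(
    network: ReactionNetwork,
    init: np.ndarray,
    t_end: float,
    dt_out: float,
    volume_scale: float,
    n_runs: int = 1,
    seed: int = 0,
    schedule: Sequence[DoseEvent] = (),
) -> tuple[Trace, Trace]:
    """Exact SSA (direct method) of the network; returns (mean, std) traces.

    ``volume_scale`` converts µM to copy numbers (counts = conc ×
    volume_scale); choose it so that copy numbers are ≳10³ when comparing
    against the deterministic solution. Trajectories are reproducible for a
    fixed ``seed``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    init = np.asarray(init, dtype=float)
    counts0 = np.round(init * volume_scale)
    needed = {sp for r in network.reactions for sp in _rate_inputs(r)}
    for sp in needed:
        if init[network.index(sp)] > 0 and counts0[network.index(sp)] == 0:
            raise ValueError(
                f"volume_scale too small: species {sp} has a zero copy number"
            )
    times = [e.time for e in schedule]
    n_out = int(round(t_end / dt_out))
    grid = dt_out * np.arange(n_out + 1)
    props, changes = _compile_propensities(network, volume_scale)
    n_rxn = len(props)

    acc = np.zeros((len(network.species), grid.size))
    acc2 = np.zeros_like(acc)
    rng = random.Random(seed)
    for _ in range(n_runs):
        n = counts0.tolist()
        out = np.empty((len(network.species), grid.size))
        gi = 0
        t = 0.0
        seg_edges = [0.0, *times, t_end]
        for k, (lo, hi) in enumerate(zip(seg_edges[:-1], seg_edges[1:])):
            if k > 0:
                ev = schedule[k - 1]
                n[network.index(ev.species)] += round(ev.amount * volume_scale)
                if ev.dilution != 1.0:
                    n = [m * ev.dilution for m in n]
            t = lo
            while True:
                a = [p(n) for p in props]
                a0 = sum(a)
                t_next = t + (rng.expovariate(a0) if a0 > 0 else math.inf)
                if t_next >= hi:
                    # flush grid points up to the segment edge; a point at
                    # a dose time reports the pre-dose state
                    while gi < grid.size and grid[gi] <= hi:
                        out[:, gi] = n
                        gi += 1
                    break
                while gi < grid.size and grid[gi] < t_next:
                    out[:, gi] = n
                    gi += 1
                r = rng.random() * a0
                cum = 0.0
                for j in range(n_rxn):
                    cum += a[j]
                    if r <= cum:
                        break
                for i, d in changes[j]:
                    n[i] += d
                t = t_next
        while gi < grid.size:
            out[:, gi] = n
            gi += 1
        conc = out / volume_scale
        acc += conc
        acc2 += conc * conc
    mean = acc / n_runs
    var = np.maximum(acc2 / n_runs - mean * mean, 0.0)
    mean_tr = Trace(time=grid, states=mean, species=network.species,
                    dose_times=tuple(times))
    std_tr = Trace(time=grid, states=np.sqrt(var), species=network.species,
                   dose_times=tuple(times))
    return mean_tr, std_tr


def _rate_inputs(rxn) -> tuple[str, ...]:
    law = rxn.rate
    if isinstance(law, MassAction):
        return law.reactants
    if isinstance(law, FirstOrder):
        return (law.species,)
    return (law.substrate,)


# --------------------------------------------------------------------------
# tidy CSV round-trip


def write_signals_csv(path, signals: Iterable[SignalTrace]) -> None:
    """Write signal traces as tidy CSV (time_min, channel, value, condition_id)."""
    frames = []
    for sig in signals:
        frames.append(pd.DataFrame({
            "time_min": sig.time,
            "channel": sig.channel,
            "value": sig.values,
            "condition_id": sig.condition_id,
        }))
    # %.17g round-trips float64 exactly
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")


def read_signals_csv(path) -> list[SignalTrace]:
    """Invert :func:`write_signals_csv` (lossless to full float precision)."""
    df = pd.read_csv(path, comment="#", keep_default_na=False,
                     float_precision="round_trip")
    out = []
    for (cid, channel), grp in df.groupby(["condition_id", "channel"], sort=False):
        out.append(SignalTrace(
            channel=channel,
            time=grp["time_min"].to_numpy(dtype=float),
            values=grp["value"].to_numpy(dtype=float),
            condition_id=str(cid),
        ))
    return out
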