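"""Synthetic plate-reader-like data with the structure the analysis assumes.

No raw traces are deposited for these circuits, so every stage of the
pipeline is exercised on synthetic data: the deterministic circuit model is
simulated under a condition and dose schedule, mapped to an optical channel,
and corrupted with the artefacts real plate-reader traces show — i.i.d.
Gaussian noise, optional linear baseline drift, and an optional transient
mixing dip locked to each dose (glycerol/DMSO mixing artefact).

``default_params`` returns the synthetic truth parameter set per circuit.
These are the generator's study conditions: one fitted-constant set per
circuit family (mirroring per-system fits), chosen so that first-cycle
lifetimes fall in the tens-of-minutes range for the individual cycles and
in the hours range for the coupled network. They are synthetic defaults,
not measured constants.

Preset suites mirror the published panel layouts: fuel titrations (1–3 eq
DNAzyme fuel, 2–4 eq trypsin fuel), exonuclease titrations, toe-hold series
(0–3 nt for Exo III, 0–12 nt for T7), repeated-dosing recyclability runs
with the published dose times, and the coupled-network reporter panel with
both optical channels.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .network import build_network
from .params import Condition, KineticParams
from .simulate import (
    DoseEvent,
    SignalTrace,
    Trace,
    integrate,
    observables,
    write_signals_csv,
)

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "default_params",
    "default_condition",
    "generate_trace",
    "suite_design",
    "build_suite",
    "regenerate_from_manifest",
    "SUITE_IDS",
]

# Dose times of the published repeated-dosing experiments (minutes).
RECYCLABILITY_DOSES_DNAZYME = (15.0, 45.5, 76.0, 106.0, 137.0, 167.5, 219.0)
RECYCLABILITY_DOSES_TRYPSIN = (
    15.0, 40.0, 71.0, 107.0, 144.0, 180.5, 216.0, 252.5, 288.5, 323.5,
    365.0, 407.0, 449.0, 488.5, 530.5, 576.5, 624.0, 677.0, 765.5, 806.0,
    884.0, 968.5, 1058.5, 1158.5, 1281.5,
)

SUITE_IDS = (
    "fuel_titration",
    "enzyme_titration",
    "toehold_series",
    "toehold_series_t7",
    "recyclability",
    "recyclability_trypsin",
    "trypsin_titration",
    "coupled_panel",
)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model for generated traces.

    ``sigma`` is the SD of additive Gaussian noise as a fraction of the
    trace's dynamic range; ``drift`` a linear baseline drift (signal units
    per minute); ``dip_amplitude``/``tau_mix`` the depth (signal units) and
    recovery time of the transient mixing dip after each dose;
    ``dt_min`` the sampling interval.
    """

    sigma: float = 0.02
    drift: float = 0.0
    dip_amplitude: float = 0.0
    tau_mix: float = 5.0
    dt_min: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.dip_amplitude != 0 and not self.tau_mix > 0:
            raise ValueError("tau_mix must be positive when a mixing dip is enabled")
        if not self.dt_min > 0:
            raise ValueError("dt_min must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseModel":
        return cls(**d)


# --------------------------------------------------------------------------
# per-circuit synthetic truth


def default_params(circuit_id: str) -> KineticParams:
    """Synthetic-truth kinetic parameters per circuit family."""
    if circuit_id in ("dnazyme_exoIII", "dnazyme_t7"):
        return KineticParams(
            k_hyb_dz=0.5, k_cat_rep=0.02, Km_rep=2.0,
            c_exo=1.0, Km_exo=5.0, beta_exo=0.5,
            c_t7=0.4, Km_t7=5.0, beta_t7=0.09,
        )
    if circuit_id in ("trypsin_exoIII", "trypsin_t7"):
        return KineticParams(
            k_hyb_apt=60.0, k_on_TA=50.0, k_off_TA=0.4,
            k_cat_try=8.0, Km_try=870.0,
            c_exo=4.0, Km_exo=2.0, beta_exo=0.5,
            c_t7=0.4, Km_t7=2.0, beta_t7=0.09,
        )
    if circuit_id == "coupled":
        return KineticParams(
            k_hyb_dz=0.5, k_cat_rep=0.03, Km_rep=2.0,
            k_cat_inh=0.056, Km_inh=2.0,
            c_exo=12.0, Km_exo=10.0, beta_exo=0.5,
            c_t7=0.8, Km_t7=10.0, beta_t7=0.09,
            k_hyb_apt=60.0, k_on_TA=50.0, k_off_TA=0.4,
            k_cat_try=8.0, Km_try=870.0,
        )
    raise ValueError(f"unknown circuit_id {circuit_id!r}")


def default_condition(circuit_id: str, **overrides) -> Condition:
    """Reference condition per circuit, following the published loadings."""
    if circuit_id in ("dnazyme_exoIII", "dnazyme_t7"):
        enzyme = "t7" if circuit_id.endswith("_t7") else "exoIII"
        base = dict(
            circuit_id=circuit_id,
            initial={"S1": 2.5, "Rep": 2.5},
            enzymes={enzyme: 0.5},
            ref_conc_uM=2.5,
        )
    elif circuit_id in ("trypsin_exoIII", "trypsin_t7"):
        enzyme = "t7" if circuit_id.endswith("_t7") else "exoIII"
        load = 0.6 if enzyme == "t7" else 0.05
        base = dict(
            circuit_id=circuit_id,
            initial={"TryApt": 0.1, "Apt": 0.9, "LBAPNA": 100.0},
            enzymes={enzyme: load},
            ref_conc_uM=1.0,
        )
    elif circuit_id == "coupled":
        base = dict(
            circuit_id="coupled",
            initial={
                "S1": 1.0, "Rep": 1.0, "InhibDuplex": 2.0,
                "TryApt": 0.05, "Apt": 0.25, "LBAPNA": 100.0,
            },
            enzymes={"exoIII": 0.025, "t7": 0.6},
            L_tryfuel=2,
            ref_conc_uM=1.0,
        )
    else:
        raise ValueError(f"unknown circuit_id {circuit_id!r}")
    base.update(overrides)
    return Condition(**base)


# --------------------------------------------------------------------------
# trace generation


def generate_trace(
    cond: Condition,
    truth: KineticParams,
    schedule: Sequence[DoseEvent],
    noise: NoiseModel = NoiseModel(),
    seed: int | Sequence[int] = 0,
    channel: str = "fluor520",
    t_end: float = 150.0,
    normalization: str = "raw",
) -> tuple[SignalTrace, SignalTrace, Trace]:
    """Simulate a condition and return (noisy signal, clean signal, states).

    With ``sigma = drift = dip_amplitude = 0`` the noisy output equals the
    noiseless truth bit for bit. Reproducible for a fixed seed.
    """
    network = build_network(truth, cond)
    trace = integrate(network, network.initial_state(cond), schedule,
                      t_end=t_end, dt_out=noise.dt_min)
    clean = observables(trace, truth, channel=channel,
                        normalization=normalization,
                        condition_id=cond.condition_id)
    values = clean.values.copy()
    t = clean.time
    if noise.dip_amplitude != 0:
        for ev in schedule:
            mask = t >= ev.time
            values = values - noise.dip_amplitude * mask * np.exp(
                -(t - ev.time) / noise.tau_mix
            )
    if noise.drift != 0:
        values = values + noise.drift * (t - t[0])
    if noise.sigma > 0:
        rng = np.random.default_rng(seed)
        dyn = float(clean.values.max() - clean.values.min())
        values = values + rng.normal(0.0, noise.sigma * dyn, size=values.shape)
    noisy = clean.replace(values=values)
    return noisy, clean, trace


# --------------------------------------------------------------------------
# preset suites


@dataclass(frozen=True)
class ExperimentDesign:
    """A bundle of conditions sharing one circuit topology and truth set."""

    suite_id: str
    conditions: tuple[Condition, ...]
    schedules: tuple[tuple[DoseEvent, ...], ...]
    truth: KineticParams
    noise: NoiseModel
    seed: int
    t_end: float
    channels: tuple[str, ...] = ("fluor520",)

    def __post_init__(self) -> None:
        if len(self.conditions) != len(self.schedules):
            raise ValueError("one schedule per condition is required")
        topologies = {c.circuit_id for c in self.conditions}
        if len(topologies) != 1:
            raise ValueError("all conditions of a suite share one circuit topology")

    def to_dict(self) -> dict:
        return {
            "suite_id": self.suite_id,
            "conditions": [c.to_dict() for c in self.conditions],
            "schedules": [
                [dataclasses.asdict(e) for e in sched] for sched in self.schedules
            ],
            "truth": self.truth.to_dict(),
            "noise": self.noise.to_dict(),
            "seed": self.seed,
            "t_end": self.t_end,
            "channels": list(self.channels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        return cls(
            suite_id=d["suite_id"],
            conditions=tuple(Condition.from_dict(c) for c in d["conditions"]),
            schedules=tuple(
                tuple(DoseEvent(**e) for e in sched) for sched in d["schedules"]
            ),
            truth=KineticParams.from_dict(d["truth"]),
            noise=NoiseModel.from_dict(d["noise"]),
            seed=d["seed"],
            t_end=d["t_end"],
            channels=tuple(d["channels"]),
        )


def _single_dose(cond: Condition, eq: float, t_dose: float = 15.0,
                 species: str = "Fuel") -> tuple[DoseEvent, ...]:
    return (DoseEvent(time=t_dose, species=species, amount=cond.eq_to_uM(eq)),)


def suite_design(suite_id: str, seed: int = 0,
                 noise: NoiseModel | None = None) -> ExperimentDesign:
    """Build the preset design for one of the published panel layouts."""
    if suite_id == "fuel_titration":
        cond = default_condition("dnazyme_exoIII")
        conds, scheds = [], []
        for eq in (1, 2, 3):
            c = cond.replace(condition_id=f"fuel_{eq}eq")
            conds.append(c)
            scheds.append(_single_dose(c, eq))
        return ExperimentDesign(
            suite_id=suite_id, conditions=tuple(conds), schedules=tuple(scheds),
            truth=default_params("dnazyme_exoIII"),
            noise=noise or NoiseModel(), seed=seed, t_end=150.0,
        )
    if suite_id == "enzyme_titration":
        conds, scheds = [], []
        for u in (0.1, 0.25, 0.5):
            c = default_condition("dnazyme_exoIII", enzymes={"exoIII": u},
                                  condition_id=f"exoIII_{u}U")
            conds.append(c)
            scheds.append(_single_dose(c, 1))
        return ExperimentDesign(
            suite_id=suite_id, conditions=tuple(conds), schedules=tuple(scheds),
            truth=default_params("dnazyme_exoIII"),
            noise=noise or NoiseModel(), seed=seed, t_end=500.0,
        )
    if suite_id == "toehold_series":
        conds, scheds = [], []
        for L in (0, 1, 2, 3):
            c = default_condition("dnazyme_exoIII", L_fuel=L,
                                  condition_id=f"toehold_{L}nt")
            conds.append(c)
            scheds.append(_single_dose(c, 1))
        return ExperimentDesign(
            suite_id=suite_id, conditions=tuple(conds), schedules=tuple(scheds),
            truth=default_params("dnazyme_exoIII"),
            noise=noise or NoiseModel(), seed=seed, t_end=400.0,
        )
    if suite_id == "toehold_series_t7":
        conds, scheds = [], []
        for L in (0, 5, 7, 10, 12):
            c = default_condition("dnazyme_t7", L_fuel=L,
                                  condition_id=f"toehold_{L}nt")
            conds.append(c)
            scheds.append(_single_dose(c, 1))
        return ExperimentDesign(
            suite_id=suite_id, conditions=tuple(conds), schedules=tuple(scheds),
            truth=default_params("dnazyme_t7"),
            noise=noise or NoiseModel(), seed=seed, t_end=500.0,
        )
    if suite_id == "recyclability":
        c = default_condition("dnazyme_exoIII", enzymes={"exoIII": 1.5},
                              condition_id="recyclability_1.5U")
        sched = tuple(
            DoseEvent(time=td, species="Fuel", amount=c.eq_to_uM(1))
            for td in RECYCLABILITY_DOSES_DNAZYME
        )
        return ExperimentDesign(
            suite_id=suite_id, conditions=(c,), schedules=(sched,),
            truth=default_params("dnazyme_exoIII"),
            noise=noise or NoiseModel(), seed=seed, t_end=300.0,
        )
    if suite_id == "recyclability_trypsin":
        c = default_condition("trypsin_exoIII", enzymes={"exoIII": 0.1},
                              condition_id="recyclability_trypsin_0.1U")
        sched = tuple(
            DoseEvent(time=td, species="FuelTry", amount=c.eq_to_uM(2))
            for td in RECYCLABILITY_DOSES_TRYPSIN
        )
        return ExperimentDesign(
            suite_id=suite_id, conditions=(c,), schedules=(sched,),
            truth=default_params("trypsin_exoIII"),
            noise=noise or NoiseModel(), seed=seed, t_end=1320.0,
            channels=("abs405",),
        )
    if suite_id == "trypsin_titration":
        conds, scheds = [], []
        for eq in (2, 3, 4):
            c = default_condition("trypsin_exoIII", condition_id=f"tryfuel_{eq}eq")
            conds.append(c)
            scheds.append(_single_dose(c, eq, species="FuelTry"))
        return ExperimentDesign(
            suite_id=suite_id, conditions=tuple(conds), schedules=tuple(scheds),
            truth=default_params("trypsin_exoIII"),
            noise=noise or NoiseModel(), seed=seed, t_end=400.0,
            channels=("abs405",),
        )
    if suite_id == "coupled_panel":
        conds, scheds = [], []
        for rep in (1.0, 2.5, 5.0):
            c = default_condition("coupled", condition_id=f"repC_{rep}uM")
            init = dict(c.initial)
            init["Rep"] = rep
            c = c.replace(initial=init)
            conds.append(c)
            scheds.append(_single_dose(c, 2, t_dose=30.0))
        return ExperimentDesign(
            suite_id=suite_id, conditions=tuple(conds), schedules=tuple(scheds),
            truth=default_params("coupled"),
            noise=noise or NoiseModel(dip_amplitude=0.1, tau_mix=5.0, dt_min=1.0),
            seed=seed, t_end=900.0,
            channels=("fluor520", "abs405"),
        )
    raise ValueError(f"unknown suite id {suite_id!r}")


def build_suite(design: ExperimentDesign, out_dir) -> dict:
    """Write one tidy CSV per condition plus a JSON manifest; returns manifest.

    Regenerating from the manifest reproduces every CSV byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for k, (cond, sched) in enumerate(zip(design.conditions, design.schedules)):
        signals = []
        for ch in design.channels:
            noisy, _, _ = generate_trace(
                cond, design.truth, sched, design.noise,
                seed=[design.seed, k, design.channels.index(ch)],
                channel=ch, t_end=design.t_end,
            )
            signals.append(noisy)
        fname = f"{design.suite_id}_{cond.condition_id or k}.csv"
        write_signals_csv(out_dir / fname, signals)
        files.append(fname)
    manifest = {"design": design.to_dict(), "files": files}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest


def regenerate_from_manifest(manifest_path, out_dir) -> dict:
    """Rebuild a suite from its manifest (byte-identical round trip)."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    design = ExperimentDesign.from_dict(manifest["design"])
    return build_suite(design, out_dir)
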