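"""Parameter and condition containers for dissipative DNA-circuit models.

Units used throughout the package: concentrations in µM, time in minutes,
enzyme loads in U·µL⁻¹, fluorescence in a.u., absorbance in AU.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any

__all__ = ["KineticParams", "Condition", "CIRCUIT_IDS"]

CIRCUIT_IDS = (
    "dnazyme_exoIII",
    "dnazyme_t7",
    "trypsin_exoIII",
    "trypsin_t7",
    "coupled",
)


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and signal-map coefficients for the circuit models.

    The same container parameterizes all three circuit topologies; fields
    that a given circuit does not use are simply ignored by its builder.

    Attributes
    ----------
    k_hyb_dz : float
        Bimolecular hybridization rate of the DNAzyme fuel with the
        protected DNAzyme strand, µM⁻¹·min⁻¹.
    k_cat_rep, Km_rep : float
        DNAzyme turnover (min⁻¹) and Michaelis constant (µM) on the
        dye/quencher reporter strand.
    k_cat_inh, Km_inh : float
        DNAzyme turnover and Michaelis constant on the inhibitor duplex
        (coupled network only); the reporter and the inhibitor share the
        DNAzyme's active site (competitive denominator).
    c_exo, c_t7 : float
        Enzyme-unit conversion constants, µM·min⁻¹ per U·µL⁻¹: the maximal
        digestion rate is ``Vmax = c · U``, attenuated per substrate by the
        toe-hold factor φ(L).
    Km_exo, Km_t7 : float
        Michaelis constants of exonuclease digestion, µM. All digestible
        substrates of one exonuclease share a competitive denominator.
    beta_exo, beta_t7 : float
        Toe-hold attenuation coefficients per nucleotide: φ(L) = exp(−β·L).
    Lmax_exo, Lmax_t7 : int
        Hard overhang cutoffs (nt) used when ``toehold_cutoff`` is set:
        Exo III initiates on overhangs of at most 4 nt, T7 up to 12 nt.
    toehold_cutoff : bool
        If true, φ(L) = exp(−β·L)·1[L ≤ Lmax] instead of the smooth default.
    k_hyb_apt : float
        Hybridization rate of free aptamer with the trypsin fuel, µM⁻¹·min⁻¹.
    k_on_TA, k_off_TA : float
        Trypsin–aptamer binding (µM⁻¹·min⁻¹) and unbinding (min⁻¹).
    k_disp : float
        Direct toehold-mediated displacement of the aptamer out of the
        trypsin complex by the fuel, µM⁻¹·min⁻¹ (0 disables the pathway).
    k_cat_try, Km_try : float
        Trypsin turnover on L-BAPNA (min⁻¹) and Michaelis constant (µM).
    alpha_F, F0 : float
        Fluorescence map: F = F0 + alpha_F·[cleaved reporter], a.u.
    eps_A, A0 : float
        Absorbance map: A = A0 + eps_A·[p-nitroaniline], AU.
    K_W : float
        Waste-inhibition constant, µM. Accumulated digestion waste scales
        the effective exonuclease Vmax by 1/(1+[W]/K_W); the default ∞
        is the ideal (waste-free) model.
    """

    k_hyb_dz: float = 0.5
    k_cat_rep: float = 0.02
    Km_rep: float = 2.0
    k_cat_inh: float = 0.056
    Km_inh: float = 2.0
    c_exo: float = 1.0
    c_t7: float = 0.4
    Km_exo: float = 5.0
    Km_t7: float = 5.0
    beta_exo: float = 0.5
    beta_t7: float = 0.09
    Lmax_exo: int = 4
    Lmax_t7: int = 12
    toehold_cutoff: bool = False
    k_hyb_apt: float = 60.0
    k_on_TA: float = 50.0
    k_off_TA: float = 0.4
    k_disp: float = 0.0
    k_cat_try: float = 8.0
    Km_try: float = 870.0
    alpha_F: float = 2.0
    F0: float = 0.0
    eps_A: float = 0.01
    A0: float = 0.0
    K_W: float = math.inf

    def __post_init__(self) -> None:
        positive = (
            "k_hyb_dz", "k_cat_rep", "Km_rep", "k_cat_inh", "Km_inh",
            "c_exo", "c_t7", "Km_exo", "Km_t7", "k_hyb_apt", "k_on_TA",
            "k_cat_try", "Km_try", "K_W",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("beta_exo", "beta_t7", "k_off_TA", "k_disp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("Lmax_exo", "Lmax_t7"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name} must be a positive integer")

    def replace(self, **changes: Any) -> "KineticParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "KineticParams":
        return cls(**d)

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "KineticParams":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        try:
            with open(source) as fh:
                return cls.from_dict(json.load(fh))
        except (OSError, ValueError):
            return cls.from_dict(json.loads(source))


@dataclass(frozen=True)
class Condition:
    """One experimental condition: initial state, enzyme loads, toe-holds.

    ``initial`` maps species names (as declared by the circuit builders) to
    initial concentrations in µM; unlisted species start at zero. Enzyme
    loads are in U·µL⁻¹ under the keys ``exoIII`` and ``t7``. Fuel amounts
    given in equivalents ("eq.") are converted through ``ref_conc_uM`` —
    the concentration of the hybridization partner of the fuel (protected
    DNAzyme strand, or the aptamer for the trypsin cycles).
    """

    circuit_id: str
    initial: dict[str, float] = field(default_factory=dict)
    enzymes: dict[str, float] = field(default_factory=dict)
    L_fuel: int = 0
    L_tryfuel: int = 0
    ref_conc_uM: float = 1.0
    condition_id: str = ""

    def __post_init__(self) -> None:
        if self.circuit_id not in CIRCUIT_IDS:
            raise ValueError(
                f"unknown circuit_id {self.circuit_id!r}; expected one of {CIRCUIT_IDS}"
            )
        for sp, conc in self.initial.items():
            if conc < 0:
                raise ValueError(f"negative initial concentration for {sp}")
        for enz, load in self.enzymes.items():
            if enz not in ("exoIII", "t7"):
                raise ValueError(f"unknown enzyme {enz!r}")
            if load < 0:
                raise ValueError(f"negative enzyme load for {enz}")
        for name in ("L_fuel", "L_tryfuel"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer")
        if not self.ref_conc_uM > 0:
            raise ValueError("ref_conc_uM must be strictly positive")

    def eq_to_uM(self, eq: float) -> float:
        """Convert fuel equivalents to µM via the reference concentration."""
        return eq * self.ref_conc_uM

    def replace(self, **changes: Any) -> "Condition":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Condition":
        return cls(**d)

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "Condition":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        try:
            with open(source) as fh:
                return cls.from_dict(json.load(fh))
        except (OSError, ValueError):
            return cls.from_dict(json.loads(source))
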