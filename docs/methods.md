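# Methods

## The systems being modeled

Three fuel-driven dissipative circuits are modeled, all built on the same
motif: a DNA fuel strand transiently activates a catalyst by hybridization,
and an exonuclease (Exo III, digesting duplexes from the 3′ end, or T7
exonuclease, from the 5′ end) digests the fuel-containing duplex and resets
the system. All concentrations are in µM, time in minutes, enzyme loads in
activity units (U·µL⁻¹).

**DNAzyme cycle.** A protected strand `S1` of a bipartite Mg²⁺-dependent
DNAzyme hybridizes with the fuel into the catalytically active duplex `Dz`,
which cleaves a dye/quencher reporter (`Rep → RepCleaved`, read out as
520 nm fluorescence). The exonuclease digests the fuel out of the duplex,
releasing `S1` intact and one unit of lumped `Waste` per duplex:

```
S1 + Fuel → Dz                   mass action, k_hyb_dz
Rep → RepCleaved                 MM catalyzed by Dz (k_cat_rep, Km_rep)
Dz → S1 + Waste                  MM, Vmax = c·U·φ(L), Km_exo/Km_t7
```

**Trypsin cycle.** Trypsin starts sequestered in a 1:10 complex with a
ssDNA aptamer; the trypsin fuel hybridizes free aptamer into the digestible
`AptFuel` duplex, pulling the binding equilibrium open; free trypsin
cleaves L-BAPNA to p-nitroaniline (405 nm absorbance). Digestion of
`AptFuel` recycles the intact aptamer, which re-silences trypsin.

**Coupled network.** The two cycles communicate unidirectionally: the
active DNAzyme cleaves, in competition with its reporter, an inhibitor
duplex that sequesters the trypsin fuel; T7 digests the cleaved inhibitor
(the intact one is protected at both ends and is not a T7 substrate) and
releases the trypsin fuel; Exo III dissipates both the DNAzyme fuel duplex
and the aptamer/fuel duplex through one shared competitive Michaelis–Menten
denominator.

## Rate-law choices

Hybridizations are irreversible mass action — the duplexes are designed not
to dissociate spontaneously. Trypsin–aptamer binding is the one reversible
step (`k_on_TA`, `k_off_TA`). All enzymatic steps are Michaelis–Menten;
where one enzyme serves several substrates (DNAzyme: reporter and
inhibitor; Exo III: both fuel duplexes), the rates share a competitive
denominator `1 + Σ_j [S_j]/Km_j`, which is what expresses the
reporter-competition effect in the coupled network. Exonuclease activity
units are mapped to a maximal rate by a fitted conversion constant,
`Vmax = c · U`, with no attempt to assign the enzymes a molarity.

Toe-hold control enters as a substrate-specific factor `φ(L) = exp(−β·L)`
on the digestion Vmax: both exonucleases initiate poorly on duplex ends
carrying single-strand overhangs, and longer overhangs slow initiation.
An optional hard-cutoff mode zeroes φ beyond the enzymes' known overhang
limits (4 nt for Exo III, 12 nt for T7); the smooth exponential is the
default because the measured length dependence is graded.

Waste (digested fuel, lumped in µM of duplex) is inert in the ideal model
(`K_W = ∞`). The fatigue extension scales the effective exonuclease Vmax
by `1/(1+[W]/K_W)`, modeling the loss of effective enzyme activity to
accumulating digestion products across repeated fuel additions.

## Simulation

`simulate.integrate` solves the ODEs with LSODA at rtol 1e−10 / atol
1e−12 µM, restarting at each dose event (instantaneous concentration jump,
optional dilution factor; a grid sample falling exactly on a dose time
reports the pre-dose state so per-cycle baselines are well defined). The
tight default tolerances keep the drift of conserved moieties below 1e−8
relative along whole trajectories; they cost little on these small (6–15
species) systems. Negative excursions are bounded by the absolute
tolerance; rate laws internally floor concentrations at zero, the reported
solution is never clipped.

`simulate.ssa_simulate` is an exact direct-method SSA over the same network
used as an independent check on the deterministic solution. Michaelis–
Menten laws enter as mean-field propensities (deterministic rate × volume)
rather than being expanded into enzyme–substrate intermediates: the
deterministic model is the object under test, and at the copy numbers used
(≳10³) the approximation error is far below the sampling noise.

## The transient-lifetime statistic

The lifetime of the activated state is read off a signal trace as on
plate-reader data: one line is fitted to the initial rise after fuel
addition, another to the plateau after fuel consumption; the deactivation
time t\* is their intersection and τ = t\* − t_dose. The construction
prescribes only "initial rise" and "plateau"; the fit windows are this
package's robustness choice, exposed in `LifetimeOptions`:

- rise: samples between 10% and 60% of the cycle amplitude above the local
  baseline, up to the first crossing of the 60% level;
- plateau: the last 25% of the cycle window; a sample qualifying for both
  windows goes to the rise fit;
- activation threshold: the amplitude must exceed 5× the plateau residual
  SD, otherwise "no activation"; parallel fits or an intersection outside
  the window give "no breakpoint"; fewer than 3 points in either fit give
  "insufficient data".

All thresholds are relative to the local baseline and amplitude, so τ is
invariant under scaling the signal and under shifting the time axis. For
repeated dosing, each cycle window spans dose-to-dose and carries its own
baseline, so cycles with partially depleted reporter are referenced
correctly. Fatigue is quantified per cycle as f_k = (τ_k − τ̂_k)/τ̂_k
against the ideal (waste-free) model re-simulated on the same schedule;
fatigue is flagged when the median defined index exceeds 0.05 and the
sequence does not decrease overall.

## Fitting

`fit_parameters` minimizes the joint weighted RSS of simulated vs observed
signals over all traces of a titration simultaneously (one shared
parameter set — the same convention used to predict unseen fuel/enzyme
loadings from a single fit). Parameters are optimized on log10 scale with
a trust-region reflective solver inside finite positive bounds;
multi-start (default 16) draws starts log-uniformly, with the geometric
center of the box as the first start. Per-trace weights are inverse noise
SDs estimated from lag-1 differences of the observed trace, which makes
the fit invariant to rescaling a channel's units. Parameters whose
residual Jacobian column is numerically zero at the optimum are reported
as non-identifiable rather than silently returned. Uncertainty, when
requested, comes from a residual bootstrap (percentile intervals) rather
than asymptotic covariance — the residuals are small and serially
correlated. Recovery experiments and the acceptance script use 2 starts:
the synthetic refits are well conditioned and more starts change nothing;
this is a problem-size choice, not a limitation of the estimator.

## Synthetic data: what it emulates, and what not

No raw plate-reader traces are deposited for these circuits, so the
generator stands in for them: deterministic circuit dynamics mapped to an
optical channel, plus i.i.d. Gaussian noise (SD a fraction of the trace's
dynamic range, default 2%), optional linear baseline drift, and an
optional transient mixing dip locked to each dose (emulating the
glycerol/DMSO mixing artefact seen in the coupled-network recordings,
where it is enabled by default in the preset). It does **not** emulate
replicate-to-replicate variance structure (real replicates share
pipetting/batch errors; the noise here is i.i.d.), instrument drift
correlated across wells, photobleaching, or temperature transients —
so passing tests demonstrate correctness of the analysis under the stated
noise model, not robustness to every artefact of real instruments.

### Synthetic-truth parameters

`default_params` returns one parameter set per circuit family — mirroring
the practice of fitting each system separately — chosen once so that the
simulated first-cycle lifetimes land in the experimentally typical range
(tens of minutes for the individual cycles at their published loadings;
hours for the coupled network). They are synthetic defaults, not measured
constants. The load-bearing choices:

- `k_hyb_dz = 0.5 µM⁻¹min⁻¹`: activation completes within a few minutes,
  clearly separated from digestion (tens of minutes) yet slow enough to be
  identifiable at 0.5-min sampling.
- `k_cat_rep = 0.02 min⁻¹` (DNAzymes are slow multiple-turnover
  catalysts): each activation cycle consumes only part of the reporter, so
  titration amplitudes grow with fuel and recyclability amplitudes decay
  gradually.
- `c_exo` differs between circuit families (1.0 for the DNAzyme cycle,
  4.0 for the trypsin cycle, 12.0 for the coupled network at its 10×
  lower Exo III load): the conversion from activity units to digested
  duplex per minute is substrate-dependent — shorter duplexes are digested
  markedly faster per strand — and is treated as a per-system fitted
  constant.
- Trypsin–aptamer: `Kd = 8 nM` (`k_on 50`, `k_off 0.4`), with fast
  fuel–aptamer hybridization (`k_hyb_apt = 60 µM⁻¹min⁻¹`, typical of
  toehold-mediated capture). The separation `k_hyb_apt·[fuel] ≫`
  aptamer-recycling flux is what lets trypsin activate even at the highest
  exonuclease load, while the small Kd keeps the baseline proteolytic leak
  to ~1% of the activated rate.
- `Km_try = 870 µM` (textbook L-BAPNA), `k_cat_try = 8 min⁻¹`: L-BAPNA
  (100 µM) is never exhausted during a cycle, so the absorbance plateau
  reflects trypsin deactivation, not substrate depletion.
- Toe-hold attenuation `β_exo = 0.5 nt⁻¹`, `β_t7 = 0.09 nt⁻¹`: a 3-nt
  overhang slows Exo III ~4.5-fold; T7 tolerates proportionally longer
  overhangs.
- Coupled network loadings: 1 µM DNAzyme strand, 2 µM inhibitor duplex,
  0.05 µM trypsin with 0.3 µM aptamer (6:1). The smaller aptamer excess
  keeps the free-aptamer buffer (0.25 µM) below the trypsin fuel released
  even under the strongest reporter competition, so the trypsin cycle
  activates across the whole reporter panel.

## Numerical choices and degenerate inputs

- Dose times must be strictly increasing and inside the simulated span;
  dose amounts non-negative; dilution in (0, 1].
- Breakpoint fits use local time (t − t_dose) for conditioning; the
  parallel-slope guard is relative (1e−9).
- The SSA requires every rate-law input species with nonzero concentration
  to map to at least one copy at the chosen volume scale.
- Tidy CSVs are written with `%.17g` and read with round-trip float
  parsing, so trace files reproduce bit-for-bit from their manifest.
- Problem sizes in the shipped tests and the acceptance script (e.g. 200
  SSA runs at 10⁴ copies, 10–20 fit replicates, 0.5–1 min sampling) are
  chosen as the smallest sizes at which the checked statistics are stable.

## Known limitations

- Digestion is a single-step duplex → products conversion; per-nucleotide
  intermediates, partially digested species (which the experiments suggest
  cause a slow late-phase drift), and sequence effects are not modeled.
- Waste is one lumped pool with a single inhibition constant; real
  digestion products affect hybridization and enzyme activity through
  several mechanisms.
- Enzyme activity is constant in time (no thermal inactivation).
- Inhibitor cleavage products are assumed to leave the DNAzyme immediately
  (no product inhibition).
- The optical maps are linear; dye photophysics are out of scope.
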