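# dissipycle

Kinetic modeling and analysis of fuel-driven, exonuclease-dissipated DNA
circuits that gate catalytic activity — a bipartite DNAzyme cycle, an
aptamer-gated trypsin cycle, and the coupled network in which the transient
DNAzyme generates the fuel for transient trypsin activation.

The package is for people building or analysing dissipative DNA circuits
who want to go from plate-reader time courses (or simulated ones) to the
quantities that characterize these systems: the **transient lifetime** of
the activated state, its dependence on fuel equivalents, exonuclease load
and toe-hold length, the kinetic constants behind it, and the **fatigue**
of the system under repeated fueling.

## The model in brief

Each circuit is a small reaction network. Fuel addition activates a
catalyst by hybridization (mass action, rate `k_hyb`); the catalyst turns
over its reporter substrate by Michaelis–Menten kinetics; the exonuclease
(Exo III or T7) digests the fuel-containing duplex with maximal rate

&nbsp;&nbsp;&nbsp;&nbsp;V<sub>max</sub> = c · U · φ(L),&nbsp;&nbsp; φ(L) = e<sup>−βL</sup>,

where `U` is the enzyme load (U·µL⁻¹), `c` a fitted unit-conversion
constant, and φ the attenuation from an `L`-nucleotide single-strand
overhang (toe-hold) on the duplex end. Substrates of one enzyme share a
competitive denominator `1 + Σ [S_j]/Km_j`. Signals are linear maps of the
cleaved-reporter species (fluorescence at 520 nm) or p-nitroaniline
(absorbance at 405 nm).

The transient lifetime τ is the plate-reader construction: intersect the
line fitted to the initial signal rise after fuel addition with the line
fitted to the plateau after fuel consumption, and subtract the dose time.

## Worked example

Simulate the Exo III–dissipated DNAzyme cycle at its reference loadings
(2.5 µM protected strand and reporter, 0.5 U·µL⁻¹ Exo III) for 1, 2 and
3 fuel equivalents dosed at t = 15 min, and extract the lifetimes:

```python
import dissipycle as dc

params = dc.default_params("dnazyme_exoIII")
cond = dc.default_condition("dnazyme_exoIII")
net = dc.build_network(params, cond)

for eq in (1, 2, 3):
    sched = (dc.DoseEvent(time=15.0, species="Fuel", amount=cond.eq_to_uM(eq)),)
    trace = dc.integrate(net, net.initial_state(cond), sched, t_end=250.0, dt_out=0.5)
    signal = dc.observables(trace, params, channel="fluor520")
    res = dc.transient_lifetime(signal, t_d=15.0)
    print(f"{eq} eq: tau = {res.lifetime:5.1f} min, amplitude = {res.amplitude:.2f} a.u.")
```

```
1 eq: tau =  19.8 min, amplitude = 0.66 a.u.
2 eq: tau =  29.2 min, amplitude = 1.38 a.u.
3 eq: tau =  41.6 min, amplitude = 2.05 a.u.
```

Lifetime grows roughly linearly with fuel: excess fuel is shuttled through
the active duplex (the protected strand is released intact by digestion
and re-binds free fuel), so the total digestion time is set by the total
fuel pool. The amplitude grows too because each cycle consumes only part
of the reporter.

The same pipeline runs from a shell. Generate a synthetic fuel-titration
suite (three tidy CSVs plus a manifest that regenerates them
byte-identically) and analyse it:

```bash
dissipycle generate --suite fuel_titration --seed 1 --out suite/
dissipycle lifetime --trace suite/fuel_titration_fuel_1eq.csv \
    --dose-times 15 --out summary.csv
```

Other pieces: `fit_parameters` (joint multi-trace weighted least squares
with multi-start and identifiability diagnostics), `recovery_experiment`
(generate → refit → per-parameter error tables), `ssa_simulate` (exact
stochastic simulation as an independent oracle for the ODE solution),
`fatigue_report` (per-cycle comparison of observed lifetimes against the
ideal waste-free model), and preset suites for enzyme titrations, toe-hold
series, repeated-dosing recyclability runs and the coupled-network
reporter panel. See `docs/methods.md` for the model, assumptions, and the
reasoning behind every default.

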