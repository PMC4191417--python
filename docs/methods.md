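# Methods

## The n-step sequential unwinding model

An enzyme–substrate complex ES converts to product through n identical,
irreversible steps (rate constant k_u, s⁻¹); from ES and every intermediate
the helicase can dissociate with rate constant k_d (s⁻¹). Dissociation is
absorbing: single-turnover conditions (a poly(dT) protein trap) prevent
rebinding, and an annealing trap prevents product re-annealing, so neither
re-association nor product decay appears in the model. Under these
assumptions the fraction unwound is the Erlang(n, k_u + k_d) CDF scaled by
the survival probability of all n steps:

    f(t) = (k_u/(k_u+k_d))^n · gammainc(n, (k_u+k_d)·t)

`gammainc` is the regularized lower incomplete gamma function, which is the
Erlang CDF; SciPy evaluates it stably in log space, so the closed form does
not overflow at large rate·time products. An independent LSODA integration
of the full species network (`solve_ode_fraction`, rtol 1e-11/atol 1e-13)
agrees with the closed form to ≤1e-8 and conserves mass to ≤1e-9; it exists
purely as a numerical cross-check.

The lag time is the threshold·amplitude crossing, i.e. a quantile of the
Erlang arrival distribution, located by bracketing plus Brent root finding
(xtol 1e-9 s). The amplitude is always the derived quantity
(k_u/(k_u+k_d))^n, never a free parameter — the model stays exactly the
stepping scheme.

## Fitting and step-count selection

Rates are fit by Levenberg–Marquardt least squares in (log k_u,
log(k_d + ε)) with ε = 1e-6 s⁻¹, which enforces positivity without
constrained optimization. Standard errors come from the local curvature
(covariance of the log parameters, mapped back by the delta method).
Initialization is deterministic: the observed plateau estimates the
amplitude, hence k_d/k_u by inversion; the time to half-plateau estimates
the Erlang median, (k_u+k_d)·t½ ≈ n − 1/3. Degenerate inputs (fewer than 4
points, or no dynamics) return a flagged, non-converged result rather than
raising.

The step count n is discrete. Candidates 1..5 are each fit; the smallest n
whose RSS is not significantly worse than the minimum-RSS candidate by an
extra-sum-of-squares F-test at α = 0.05 (1 numerator df for the structural
parameter) is selected — the most parsimonious adequate mechanism. For a
single curve the error variance is the best fit's RSS/(N−3). When replicate
curves on a common grid are supplied, the fit uses their pointwise mean
(the same least-squares minimizer as pooling) and the F-test denominator
uses the replicate pure error — the classical lack-of-fit construction,
which is model-free and better resolved than a residual-based estimate.

Power analysis of this selection under the packaged study conditions
(20 log-spaced times over 5–500 ms, noise sd 0.02, 3 replicates): the
fork condition (n = 2, plateau 0.45) is identified essentially always,
while the junction condition (n = 3, plateau 0.25) is intrinsically harder —
the noncentrality of the n=2-vs-n=3 contrast is ≈ 8.7, so even a
known-variance likelihood-ratio test identifies n = 3 in only ~78% of
simulations. Pooled over the two conditions the expected recovery rate is
~85–90%, and the corresponding end-to-end test in this package measures
88/100 under its fixed seeds. Median relative error of k_u in the same
study is ~2%. This is a property of the experimental design (amplitude,
noise, sampling), not of the fitting code; recovery improves quickly with
lower noise, more replicates, or higher amplitude.

### Step-size and velocity arithmetic

m = (L − L₀ − L_B)/n is computed as an exact rational; for display, integer
values print plain and fractional values are truncated toward zero at two
decimals (8/3 → "2.66", matching tabulated usage). V_un = m·k_u; tabulated
velocities are reproduced by rounding half away from zero to integer bp/s.
In the packaged reference table all integer-m rows reproduce exactly; m = 8/3
rows reproduce within ±1 bp/s except one row (printed 171 vs recomputed 169),
whose printed value is internally inconsistent with its own k_u and m — the
report flags it.

## Fork-binding species partition

A fork carries two single-stranded arms modeled as independent binding
sites with dissociation constants Kd5 (productive, 5′) and Kd3
(non-productive, 3′); a junction has only the 5′ site. Species weights at
free-enzyme concentration x are 1, x/Kd5, x/Kd3 and c·x²/(Kd5·Kd3) (c = an
optional cooperativity multiplier on double occupancy, default 1). Free
enzyme solves E_free + D5 + D3 + 2·D53 = E_total, a strictly monotone
equation bracketed on [0, E_total] and solved by Brent to machine precision
(conservation residuals ≤1e-10 nM). Predicted ssDNA product weights the
productively engaged species by its unwinding amplitude: A_fork·(D5 + D53)
for forks, A_junction·D5 for junctions. Equal default affinities
(Kd5 = Kd3) reflect the absence of any observed arm preference; equilibrium
(not kinetic) occupancy is appropriate because enzyme and DNA are
pre-incubated for minutes before ATP addition. Default amplitudes 0.45/0.25
mirror the fork/junction progress-curve plateaus. Kd values are
configuration inputs, not asserted constants; packaged defaults (10 nM) are
synthetic choices of a plausible tight-binding scale.

This model reproduces the qualitative product-amplitude reversal: with
A_fork > A_junction the fork out-produces the junction when enzyme is in
excess (every 5′ arm occupied), and under-produces it when substrate is in
excess (enzyme titrated away onto 3′ arms).

## Footprint quantification

Band intensities are normalized to the lane total, so differing exposures
cancel; relative reactivity is the ratio of with-protein to without-protein
lane fractions, averaged over paired replicates with sample sd. A zero
without-protein fraction yields NaN ("undefined"), never infinity. Calls
use strict thresholds (default protected < 0.8, enhanced > 1.2; boundaries
neutral); the defaults are configurable since published calls are
qualitative. Note one structural consequence of lane normalization: a
uniform protection factor p at some positions appears as
p·Σbase/Σ(base·p) — slightly above p — and unprotected positions rise
correspondingly; the generator's truth record carries this renormalized
oracle so round-trip tests are exact.

## Titration correction and Hill fit

ΔF = (F_raw − F_buffer_blank) − (F_protein_only − F_protein_only[0]): the
buffer blank removes dilution, the anchored protein-only series removes
protein autofluorescence (zero before the first addition). The correction
is exactly linear. ΔF is fit to F_max·cʰ/(K½ʰ + cʰ) by lmfit with
deterministic initialization (F_max from the max signal, K½ from the
concentration nearest half-max, h = 1). A saturation warning fires when the
maximum signal sits at the last titration point and the terminal slope still
exceeds 10% of the steepest slope — in that case F_max and K½ are
extrapolations. Concentration units are taken as given in the input and
never converted silently; packaged fixtures use K½ = 330 and h = 1.9 in
generic concentration units.

## Synthetic data generator

One integer seed expands into per-stage independent substreams via
`SeedSequence(seed, spawn_key=(stage,))` with a fixed append-only stage
table, so adding a generator never perturbs existing fixtures. Defaults
encode the study conditions: 20 log-spaced times over 0.005–0.5 s, Gaussian
quantification noise sd 0.02 (clipped to the raw ingest range
[−0.05, 1.05]), 3 replicates; fork truth n = 2, k_u = 71.9 s⁻¹ and junction
truth n = 3, k_u = 78.4 s⁻¹ with k_d set from the observed plateaus via
k_d = k_u(A^(−1/n) − 1), because dissociation rate constants are not
tabulated anywhere and the plateau is the observable that pins them.
Footprint lanes use a 9-position thymidine tract with mild junction-style
protection across positions 2–6 and strong (0.4) protection at positions
8–9 — the fork-specific signature — multiplicative lognormal band noise
(CV 5%) and a random per-lane exposure. Titrations add a linear protein
background, a 0.5%-per-addition dilution decay on the labeled-DNA series,
and Gaussian noise (default CV 2% of F_max); the protein-only control's DNA
term is constant so that the standard correction recovers the pure Hill
signal exactly at zero noise.

What the generator does **not** emulate: sequence-dependent base-pair
stability, shot noise of radiometric detection, gel-resolution artifacts,
inner-filter effects, or kinetic (non-equilibrium) binding during
pre-incubation. Passing round-trip tests therefore demonstrates estimator
correctness under the stated noise model, not robustness to every artifact
of real gels and fluorimeters.

## Problem sizes used in the packaged studies

Parameter-recovery studies run 50 seeded simulations per substrate condition
(100 total) at the default design; the Hill noise study runs 50 seeded fits;
the closed-form/ODE equivalence check draws 30 random mechanisms (n ≤ 6,
rates ≤ 500 s⁻¹); the footprint sampling-sd oracle uses 200 Monte-Carlo
triples. All are the package's own choices of study size.

## Known limitations

* The stepping model assumes identical, irreversible steps and a single
  bound helicase; cooperative multi-enzyme stepping appears only through
  its equilibrium-binding consequences.
* Step-count selection inherits the identifiability limits quantified
  above; n reported for low-amplitude, noisy curves should be read together
  with its per-candidate F-table rather than as ground truth.
* The binding partition allows at most one enzyme per arm and does not
  model the three-enzyme occupancy suggested by saturating-footprint
  patterns.
* Footprint inputs are already-quantified band tables; densitometry is out
  of scope.
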