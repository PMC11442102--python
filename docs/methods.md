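# Methods

## The model

`pvcal` simulates and calibrates a two-state lumped-parameter model of the
left ventricle (LV) and proximal systemic circulation, sized for murine
hemodynamics. The LV is a time-varying linear elastance,

    P_lv(t) = E(t) · (V_lv(t) − V_lv,d),

filled from a constant left-atrial pressure source P_la through a mitral
resistance R_mv and ejecting through an aortic valve resistance R_av into a
single compliant aortic compartment (compliance C_ao) that drains through an
arterial resistance R_art into a constant capillary pressure P_cap. Both
valves are ideal diodes, Q = max(ΔP/R, 0). The states are LV volume V_lv
(µL) and aortic pressure P_ao (mmHg):

    dV_lv/dt = Q_mv − Q_av
    dP_ao/dt = (Q_av − Q_sys) / C_ao,   Q_sys = (P_ao − P_cap)/R_art

Aortic volume is never materialised; P_ao = V_ao/C_ao is absorbed into the
state. The elastance is a two-piece cosine ramp, continuous and periodic
with the cycle length T:

    E(t) = E_ed + (E_es − E_ed)/2 · (1 − cos(π t/T_s)),        0 ≤ t < T_s
         = E_ed + (E_es − E_ed)/2 · (1 + cos(π (t−T_s)/(T_e−T_s))),  T_s ≤ t < T_e
         = E_ed,                                               T_e ≤ t < T

so E attains its peak E_es exactly at the time of maximum elastance T_s and
returns to the diastolic floor E_ed at the time of minimum elastance T_e.

### Parameters

Nine inferable parameters, θ = {R_mv, R_av, R_art, E_es, E_ed, T_s, T_e,
V_lv,d, C_ao}, plus three fixed constants (defaults P_la = 5 mmHg,
P_cap = 20 mmHg, T = 0.11 s). Default a priori values and ranges:

| name   | units      | a priori | range            | meaning                       |
|--------|------------|----------|------------------|-------------------------------|
| R_mv   | mmHg·s/µL  | 5e-3     | [1e-4, 1e-2]     | mitral valve resistance       |
| R_av   | mmHg·s/µL  | 1e-3     | (held fixed)     | aortic valve resistance       |
| R_art  | mmHg·s/µL  | 2.68e-1  | [0.1, 1.0]       | arterial resistance           |
| E_es   | mmHg/µL    | 4.85     | [0.5, 6.0]       | end-systolic elastance        |
| E_ed   | mmHg/µL    | 1.46e-1  | [1e-2, 1.0]      | end-diastolic elastance       |
| T_s    | s          | 4.40e-2  | [0.0363, 0.0726] | time of maximum elastance     |
| T_e    | s          | 7.70e-2  | [0.0726, 0.0968] | time of minimum elastance     |
| V_lv,d | µL         | 5        | [1, 10]          | LV dead volume                |
| C_ao   | µL/mmHg    | 9.68e-1  | [0.4, 1.5]       | aortic compliance             |

Timing ranges are fractions 0.33–0.66 and 0.66–0.88 of the cycle length
expressed in seconds. A priori rules from data: E_es = max(P_lv)/min(V_lv),
E_ed = min(P_lv)/max(V_lv), R_art = (mean(P_ao) − P_cap)/CO, C_ao = stroke
volume / aortic pulse pressure; T_s and T_e from the extrema of dP_lv/dt
with fallbacks 0.044 s and 0.077 s.

### Numerics

The periodic steady state is found by integrating beat after beat from a
fixed initial state (V_lv = 40 µL, P_ao = 70 mmHg) until the sampled
(V_lv, P_ao) trajectories of consecutive beats differ by less than
tol = 1e-6 in amplitude-relative sup norm (max 50 beats; typically ~25 from
cold, 1–3 when warm-started). The integrator is a classical fixed-step RK4
compiled with numba, with the step chosen from the circuit's fastest linear
relaxation times (dt ≤ 0.25·min{R_mv/E_es, R_av/E_es, R_av·C_ao,
R_art·C_ao}, and at least 10 substeps per output sample). A fixed step makes
every solve bit-deterministic — which the multistart, MCMC and coverage
machinery rely on — and the step rule keeps the valve-switching transients
resolved anywhere in the admissible parameter box. Accuracy is audited by
the step-halving test (outputs change by < 1e-4 relative) and by the
periodic flow-balance identity ∫Q_mv dt ≈ ∫Q_av dt. The diode kinks live in
the derivative only; no event detection is used. The converged beat is
resampled on the measurement grid t_k = k/f_s (f_s = 500 Hz → 55 samples
per 0.11 s beat, endpoint excluded).

A solver failure (non-finite state) inside calibration is converted to a
flat sentinel residual vector with squared norm 1e12 so optimizers and
samplers can route around pathological parameter sets.

## Synthetic data

`synthesize_dataset` emulates an averaged single-beat murine
pressure–volume recording: three aligned signals (V_lv, P_lv, P_ao) over
one 0.11 s cycle at 500 Hz, generated from a converged model beat plus one
of three measurement-error models (per-signal independent streams from one
seeded generator):

- **iid**: ε_k ~ N(0, σ²), default σ = 2 in each signal's units — chosen as
  a realistic few-percent noise floor relative to the murine signal
  amplitudes (~15 µL stroke volume, ~60 mmHg systolic pressure);
- **heteroskedastic**: independent Gaussian with sd σ·(1 + γ·t_k) — a
  linear-in-abscissa law, the simplest one-parameter realisation of
  variance growing along the record;
- **correlated**: stationary lag-1 autoregressive errors with coefficient ρ
  and marginal sd σ — the standard one-parameter model of serial
  dependence.

The generator does **not** model beat-to-beat variability, drift, or
catheter artefacts, so passing tests demonstrate correctness of the
inference machinery under its own stated error models, not robustness to
real-instrument pathologies. The default generating truth is the a priori
parameter set above ("mouse-like" conditions). The quadratic testbed
M(x) = 0.4x² − 0.1x + 2 carries the same noise machinery over an arbitrary
abscissa for error-model work that needs no ODE.

## Sensitivity, ranking and subset selection

Local sensitivities are central differences with relative step h = 1e-4
(balancing truncation error against the integrator's discretisation noise).
Scaled entries use relative parameter scaling and data-mean output scaling,
S_{k,i}(t) = (∂y_k(t)/∂θ_i)·θ_i/ȳ_k, making the ranking ∑_{t,k} S²
unit-free across resistances, elastances, times and volumes. Parameter
interdependence comes from the covariance proxy C = (SᵀS)⁺ converted to a
correlation matrix. Subset selection fixes (a) parameters scoring below
1e-3 of the top score and (b) the lower-ranked member of any pair with
|corr| > 0.95, with deterministic tie-breaks. Under mouse-like conditions
this reproduces the reference analysis: R_av is ranked last and fixed, and
E_es–V_lv,d correlate at ≈0.96, fixing the dead volume and leaving seven
free parameters.

Profile likelihood re-optimises all other free parameters at each grid
value of the target (warm-started along the sweep, L-BFGS-B). The
threshold is the Gaussian-approximation cost ratio J*·(1 + χ²_{1−α,1}/(n−p));
a curve crossing it on both sides of the minimum is classified
identifiable, on one side one-sided, never flat.

## Frequentist calibration

The cost is the unweighted OLS sum over the three stacked signals (the
signals are deliberately not rescaled — volumes in µL and pressures in mmHg
are of comparable magnitude here). Multistart optimization draws initial
points uniformly from the bound box (redrawing the measure-zero-cost draws
that violate ordering invariants such as E_es > E_ed), refines each with a
trust-region-reflective bounded least-squares solver (tolerances 1e-10, max
2000 residual evaluations), and sorts by cost. The coefficient of variation
of each parameter over the top-k fits (k = 20 by default, sample sd / mean)
is the practical-identifiability summary. Information criteria use the
Gaussian profile-likelihood forms AIC = n·ln(J/n) + 2(p+1) and
BIC = n·ln(J/n) + ln(n)·(p+1), counting the noise variance as an estimated
parameter and dropping additive constants (which cancel in comparisons).

## Bayesian calibration

Likelihood: −(n/2)·ln(2πσ²) − J(θ)/(2σ²) with a single shared variance
across the three signals (the Bayesian counterpart of the unweighted cost);
priors are uniform boxes on the parameter ranges. Sampling is adaptive
Metropolis: Gaussian random walk whose covariance, after a 1,000-iteration
warm-up, tracks s_d·cov(history) + s_d·ε·I with s_d = 2.4²/p and ε = 1e-10,
updated every iteration from a running Welford recursion; the initial
proposal sd is 1% of each prior width. σ² is refreshed each iteration from
its conjugate inverse-gamma conditional IG(a₀ + n/2, b₀ + J/2), with a weak
prior (n₀ = 1) anchored at the starting point's mean squared residual.
Burn-in is 20% by default. Marginal modes are kernel-density peaks
(Gaussian KDE, Silverman-class bandwidth, 512-point grid). Effective sample
size uses the autocorrelation sum truncated at the first non-positive lag.

## Uncertainty quantification

Frequentist: σ̂² = J(θ̂)/(n−p); parameter covariance σ̂²(FᵀF)⁻¹ with F the
unscaled central-difference Jacobian at the optimum; CIs use
t_{1−α/2, n−p}. Output bands follow the delta method — confidence
half-width t·σ̂·√(gᵀ(FᵀF)⁻¹g) and prediction half-width with (1 + ·) —
and reduce exactly to the classical linear-regression formulas when the
model is linear in its parameters (checked against statsmodels OLS).
A Gram matrix with condition number above 1e12 raises an identifiability
error naming the most collinear sensitivity pair.

Bayesian: the post-burn-in chain is thinned uniformly to 2,000 draws; each
(θ, σ²) draw is pushed through the simulator; credible bands are pointwise
2.5/97.5 percentiles of the simulations, prediction bands add per-draw
Gaussian noise, and the centre curve is the simulation at the retained
maximum-posterior sample.

Residual diagnostics flag non-iid errors when the lag-1 autocorrelation
leaves the 2/√n white-noise band or when a straight-line regression of
squared residuals on the abscissa has a significant slope. Because the two
checks are OR-combined, the slope component runs at α/2 (Bonferroni) so the
family false-alarm rate of the iid verdict stays near the nominal 5%.

## Problem sizes used in the test suite

Simulation-heavy checks are sized to be statistically meaningful at a
deliberate scale: 20-start noiseless recovery; 200 replicates for
parameter-CI coverage (each refit by one bounded least-squares run started
at the generating truth — the recovery test separately establishes that
multistart reaches the same optimum from random starts); 50 replicates for
prediction-band coverage; a 30,000-iteration chain for the analytic
2-D Gaussian sampler check and a 5,000-iteration cardiac chain for the
mode/optimum agreement; 8 replicates × 2,000 iterations for the reduced
credible-coverage replication; 100 repeats per error model for the
diagnostic verdicts.

## Known limitations

- No atrial dynamics, baroreflex, pericardium, valve inertia or
  regurgitation, or multi-compartment vasculature; constant cycle length.
- The residuals of the calibrated model on real recordings are not
  expected to be iid (model discrepancy); no discrepancy correction is
  implemented — the diagnostics only detect the violation.
- Local (derivative-based) sensitivity only; conclusions hold near the
  evaluation point.
- Single-chain MCMC; between-chain diagnostics (e.g. Gelman–Rubin) are out
  of scope.
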