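# pvcal

Simulation, sensitivity analysis, identifiability assessment, and
frequentist/Bayesian calibration of a lumped-parameter left-ventricle/aorta
model against pressure–volume data.

`pvcal` is aimed at cardiovascular modellers who want a complete,
reproducible parameter-inference workflow on single-beat hemodynamic
recordings (the defaults are sized for murine data: one 0.11 s cycle
sampled at 500 Hz). The package contains the forward model, a synthetic
data generator with three measurement-error models, and every analysis
stage from parameter screening to posterior prediction bands.

## The model

A two-state circuit analog of the left heart and proximal circulation.
The left ventricle is a time-varying linear elastance,
P_lv = E(t)·(V_lv − V_lv,d), with E(t) a continuous two-piece cosine ramp
between the diastolic floor E_ed and the end-systolic peak E_es (reached at
time T_s, back to baseline at T_e). It fills from a constant atrial
pressure P_la through a diode mitral resistance R_mv and ejects through a
diode aortic resistance R_av into a compliant aortic compartment C_ao that
drains through the arterial resistance R_art into a constant capillary
pressure P_cap:

    dV_lv/dt = Q_mv − Q_av,      Q = max(ΔP/R, 0) across each valve
    dP_ao/dt = (Q_av − Q_sys)/C_ao,   Q_sys = (P_ao − P_cap)/R_art

Calibration minimises the unweighted least-squares mismatch of the three
signals (V_lv, P_lv, P_ao),

    J(θ) = Σᵢ (Dᵢ^V − V_lv(tᵢ;θ))² + Σᵢ (Dᵢ^P,lv − P_lv(tᵢ;θ))² + Σᵢ (Dᵢ^P,ao − P_ao(tᵢ;θ))²,

by multistart bounded least squares (frequentist) or samples the Gaussian
likelihood with uniform box priors and a conjugately-updated noise variance
by adaptive Metropolis (Bayesian). See `docs/methods.md` for the full
account.

## Worked example

```python
import numpy as np
from pvcal import PVModel, ModelParameters, NoiseSpec, synthesize_dataset

# mouse-like synthetic beat: a priori truth + iid noise, sd 2
truth = ModelParameters()
noisy, clean = synthesize_dataset(truth, noise=NoiseSpec(kind="iid", sigma=2.0, seed=7))

model = PVModel(noisy)                      # 7-parameter free subset
free, fixed = model.select_subset()         # sensitivity-based screening
print(fixed)
# {'r_av': 'noninfluential (score < 0.001 of max)',
#  'v_lv_d': 'correlated (|corr|=0.965) with higher-ranked e_es'}

res = model.fit(n_starts=100, seed=0)       # multistart least squares
print(res.summary().round(4))
#        estimate      se   lower   upper  cov_top20_pct
# r_mv     0.0046  0.0007  0.0033  0.0059            0.0
# r_art    0.2615  0.0091  0.2436  0.2794            0.0
# e_es     5.0437  0.1192  4.8082  5.2791            0.0
# e_ed     0.1540  0.0116  0.1310  0.1769            0.0
# t_s      0.0448  0.0006  0.0437  0.0460            0.0
# t_e      0.0766  0.0006  0.0755  0.0778            0.0
# c_ao     1.0170  0.0736  0.8716  1.1623            0.0
print(round(res.sigma2_hat, 3))             # 3.223 — estimates σ² (truth 4)
print(res.information_criteria())           # AIC 201.9, BIC 226.8

bayes = model.fit_bayes(n_iter=5000, seed=0)   # adaptive Metropolis
print(bayes.chain.acceptance_rate)             # 0.249 after adaptation
bands = bayes.output_bands(n_draws=500)        # credible + prediction bands
```

Every interval above contains its generating value (e.g. true
r_art = 0.268, e_es = 4.85, t_s = 0.044); the vanishing top-20
coefficients of variation show the 20 best of 100 starts agreeing to
numerical precision — a unique global minimum — and the posterior modes
agree with the frequentist optimum.

A command-line driver mirrors the library
(`pvcal run --config cfg.json --seed 0 --out run/` executes the full
simulate → sensitivity → subset → fit → mcmc → uq pipeline and writes every
stage artifact as CSV/JSON with provenance).

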