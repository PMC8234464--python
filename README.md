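# navpop

Population-level modelling of the human atrial voltage-gated Na⁺ channel
(Na_v1.5).

Voltage-clamp measurements of I_Na in human atrial myocytes are scattered
across publications that differ in bath temperature, Na⁺ concentrations,
pulse protocols and un-documented lab practice.  Fitting a channel model to
any single source throws most of that information away and bakes one lab's
conditions into the model.  `navpop` instead fits **one hierarchical Bayesian
model across all experiments at once**: every experiment gets its own set of
biophysical parameters, and those sets are tied together by a population-level
regression with a temperature covariate and per-paper random offsets.  The
fitted population distribution is then the natural source for a
*population of models* — an ensemble of channel parameterisations representing
physiological cell-to-cell variability — whose emergent behaviour can be
validated in single-cell and 1-D fiber action-potential simulations.

## The model

**Channel.**  A hybrid Markov/Hodgkin–Huxley Na_v1.5 model with 8 state
variables in three independent modules: a two-state activation pair
(O_m ⇌ C_m), and fast and slow inactivation chains A ⇌ C ⇌ I whose A⇌C
transitions use the shared inactivation steady state h_ss with module-specific
time constants (τ_h,f, τ_h,s), and whose C⇌I (recovery) transitions share
j_ss/τ_j.  The open probability is

    P_open = O_m³ · [A_hf·A_f + (1 − A_hf)·A_s],      I_Na = G_Na · P_open · (V − E_Na)

Steady states are logistic in voltage, e.g. m_ss = 1/(1 + exp(−(V + m_shift)/m_slope));
time constants are bi-exponential, τ(V) = b·baseline + τ_max/(e^{(V−δ)/s₁} + e^{−(V−δ)/s₂})
with baseline scales b = 1/15, 1/10, 1, 1 for the m, h_f, h_s, j gates.  All
25 parameters are driven by unconstrained *factors* (exponential transform for
positive parameters, logistic for A_hf, identity for shifts).

**Statistics.**  Observed curves are the simulated protocol output plus
Gaussian noise with an experiment-kind-specific σ.  Per-experiment factor rows
follow

    P_i ~ N₂₅( β₀ + β_T·(T_i − 17 °C) + u_paper(i),  Σ ),   u_p ~ N(0, diag(σ²_UVEP))

where u_p is the per-paper "UVEP" offset (undefined variability in
experimental protocol) and Σ is a full 25×25 covariance.

**Sampler.**  Hyperparameters have tractable conditionals and are Gibbs
updated (conjugate Gaussian draws for β₀/β_T/u_p, inverse-Wishart for Σ, slice
sampling for the scale parameters).  The factor rows — whose likelihood
requires simulating voltage-clamp protocols — use adaptive random-walk
Metropolis–Hastings tuned per experiment toward a 0.234 acceptance rate, plus
a crossover move every 10 iterations that copies a random ~10 % factor subset
from a donor experiment in the same paper- or kind-group.

## Worked example

```python
import numpy as np
from navpop import (BathConditions, FactorVector, transform_factors, nernst,
                    run_iv, normalize_iv, default_protocol)
from navpop.synthetic_data import reduced_truth, generate_dataset, recovery_report
from navpop.hier_stat import HierModel
from navpop.mcmc_engine import FitConfig, run_chain

params = transform_factors(FactorVector.default())
bath = BathConditions(temperature=22.0, Na_out=50.0, Na_in=9.1)
print(f"E_Na = {nernst(bath):.1f} mV")

iv = run_iv(params, default_protocol("IV", bath))
print(f"IV peak at {iv.x[np.argmin(iv.y)]:.0f} mV")

truth = reduced_truth(seed=0)                  # 3 papers, 9 experiments
ds, latents = generate_dataset(truth)
chain = run_chain(HierModel(ds, space=truth.space),
                  FitConfig(iterations=600, warmup=300, thin=10, seed=1))
rep = recovery_report(truth, chain, latents)
print(f"coverage of 90% CIs: {rep.coverage:.2f}")
print("posterior error stds:",
      ", ".join(f"{k}={v:.3f}" for k, v in rep.sigma_exp_posterior.items()))
```

prints

```
E_Na = 43.3 mV
IV peak at -20 mV
coverage of 90% CIs: 0.88
posterior error stds: IV=0.243, SSA=0.041, SSI=0.039, REC=0.039
```

`E_Na` is the Nernst reversal potential for the reduced-Na⁺ bath; the IV curve
peaks around −20 mV as expected for Na_v1.5.  On synthetic data the 90 %
credible intervals for the population mean cover the generating truth for 7 of
8 free factors on this seed, and the fitted per-kind error magnitudes echo the
generating structure (IV curves noisiest by far).

A command-line interface mirrors the pipeline:

```sh
navpop synth --scale reduced --seed 3 --out data/
navpop validate-data data/dataset.json
navpop fit --data data/dataset.json --config fit.yaml --out chain/
navpop population --fit chain/ --n 100 --temp 37 --seed 7 --out pop/
navpop tissue --pop pop/population.jsonl --mode fiber --bcl 1000 --out cv.csv
```

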