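# Methods

## Channel model

The Na_v1.5 model has 8 occupancy state variables in three conserved modules.
The activation pair (O_m, C_m) is mathematically a Hodgkin–Huxley *m* gate:
its transition rates are α_m = m_ss/τ_m toward the open state and
β_m = (1 − m_ss)/τ_m back, so O_m relaxes mono-exponentially to m_ss with time
constant τ_m and enters the open probability as O_m³.  Each inactivation
module is a linear three-state chain A ⇌ C ⇌ I.  The A⇌C transition is
governed by the shared inactivation steady state h_ss with the fast (τ_h,f) or
slow (τ_h,s) time constant; the C⇌I transition represents recovery and uses
j_ss/τ_j identically in both chains, so recovery kinetics are common to the
fast and slow pathways.  Rates are obtained from each (steady state, time
constant) pair by the standard two-state equivalence α = ss/τ, β = (1 − ss)/τ,
which reproduces the pair's stationary ratio and relaxation time exactly.
Chain stationary occupancies follow from detailed balance and are computed in
closed form (weights h·j : (1−h)·j : (1−h)(1−j)), which is also how protocol
simulations are initialised at the holding potential.

The driving force is ohmic, I = G_Na·P_open·(V − E_Na), with E_Na from the
Nernst equation at the recording bath's temperature and Na⁺ concentrations.
Temperature affects the model only through E_Na and the statistical layer's
covariate — the channel ODEs themselves carry no Q10 scaling.

### Parameters

The 25 factors are unconstrained reals; the transform layer maps them to the
biophysical scale (exponential for conductance, slopes, τ maxima and the
shared baseline; logistic for the fast fraction A_hf; identity for voltage
shifts).  The package's reference parameterisation (`DEFAULT_FACTORS`)
describes a plausible human atrial Na_v1.5: activation midpoint −40 mV
(slope 7 mV), inactivation/recovery midpoints −82 mV (slope 6 mV), τ maxima
0.4 ms (m), 8 ms (h_f), 60 ms (h_s), 150 ms (j), a 1 ms shared baseline
(scaled 1/15, 1/10, 1, 1 per gate) and A_hf ≈ 0.9.  The depolarised-side τ
slopes for both inactivation chains are set to 30 mV so that inactivation does
not accelerate to its baseline floor too early; with the floors fixed at
baseline/10 versus baseline/15 for the m gate, a steeper decline would bend
the peak-conductance curve back down within the activation protocol's range.

## Voltage-clamp protocols

Five experiment kinds are simulated: IV families (signed peak current per
step), steady-state activation (min–max-normalised peak conductance,
steps −100…0 mV), steady-state inactivation (conditioning pulse then test
pulse, normalised to the most negative conditioning potential), two-pulse
recovery (P2/P1 peak ratio), and sampled current traces.  The default voltage
grid is −100…+60 mV in 10 mV steps with −120 mV holding and 30 ms test
pulses; the activation grid stops at 0 mV because beyond it the driving force
shrinks and depolarised inactivation makes the measured conductance
non-monotone, which is also why experimental activation protocols rarely go
further.

Two integration back ends share one contract.  The *bdf* back end integrates
the gating ODEs with scipy's implicit backward-differentiation solver at
rtol 10⁻³ / atol 10⁻⁶ and locates peaks on the dense output with local
quadratic refinement.  The *analytic* back end (default) exploits the fact
that the whole gating system is linear at constant voltage: each pulse
segment is solved exactly (closed form for the activation pair, batched
eigendecomposition of the two 3×3 chain generators), the peak is bracketed on
a coarse grid concentrated over the first 8 ms and refined by a vectorised
fine scan plus quadratic interpolation.  A test asserts the two back ends
agree on IV peaks to well under 1 %.  The analytic path exists because the
sampler's likelihood evaluates hundreds of protocol simulations per second;
it is exact up to the peak-location tolerance, not an approximation of the
ODE solution.

Normalisation follows the curation rules: IV curves not normalised to cell
capacitance are scaled so the minimum is −1, then the signed square root
sgn(x)·√|x| tempers large values (capacitance-normalised curves get the
signed square root only).  The empirical reversal potential is the linearly
interpolated zero crossing on the depolarised limb; IV records whose
empirical reversal deviates from the Nernst prediction by more than 10 mV
are excluded, smaller deviations shift the record's voltage axis so the
empirical reversal coincides with the Nernst value.

## Hierarchical statistical model

All densities live on the unconstrained factor scale.  Experiment-level:
observed curve = simulated curve + i.i.d. N(0, σ²_kind) noise, one σ per
experiment kind.  Parameter-level: P_i ~ N(β₀ + β_T·T_i + u_paper(i), Σ) with
T_i the bath temperature minus 17 °C, and u_p ~ N(0, diag(σ²_UVEP)) the
per-paper offset — the zero-mean prior keeps the offsets summing softly to
zero and prefers small inter-paper corrections.

Priors: β₀,j ~ N(m_j, 5²) centred on the reference factors (a zero-centred
prior would be nonsensical for the shift factors, which are untransformed and
sit at tens of mV); β_T,j ~ N(μ_lit,j, 0.5²) where μ_lit encodes Q10-type
literature expectations (−0.1 per °C on log-τ maxima and baseline,
+0.04 per °C on log-conductance, 0 elsewhere); σ_UVEP,j and the per-kind
error stds are Half-Normal(1); Σ ~ Inverse-Wishart(ν = K + 4,
Ψ = 0.01·(ν − K − 1)·I), i.e. a weakly informative prior with mean 0.01·I
(per-factor sd 0.1 on the factor scale).  The inverse-Wishart was chosen over
a separation-strategy (scale × correlation) prior because it gives the
covariance an exact conjugate Gibbs update in a sampler that has no gradient
backend; its mild tail behaviour is acceptable at these dimensions and is
covered by the parameter-recovery study.

Inference may be restricted to a *free* subset of the 25 factors
(`FactorSpace`); pinned factors stay at the reference values.  The map from
(record, factor row) to a predicted curve is injectable, so tests replace the
biophysics with an identity map to obtain a conjugate linear-Gaussian
reduction with a closed-form maximiser.

## Sampler

Each iteration: (1) a Gibbs sweep over the hyperparameters — joint conjugate
Gaussian draw of (β₀, β_T) with the Kronecker-structured precision, conjugate
draws of the u_p rows, slice sampling for σ_UVEP,j and σ_kind, inverse-Wishart
draw of Σ — none of which needs protocol simulations; (2) one adaptive MH
step per experiment row with jump MVN(0, scale²·C_i); (3) every 10th
iteration, a crossover move per experiment: a Bernoulli(0.10) mask over the
factors (expected 2.5 of 25 selected), a donor drawn uniformly from the
experiment's paper-group or kind-group (partition chosen uniformly), masked
factors copied from the donor, accepted by the Metropolis ratio.  The copy
semantics follow the method being reproduced; a copy proposal is not exactly
symmetric (the reverse proposal has zero density once the old values are
overwritten), so the crossover is a pragmatic mixing device rather than an
exactly balanced kernel — the exactly-correct moves (MH rows, Gibbs sweeps)
dominate the chain, and degenerate crossovers (empty mask, self-donor) are
identities.

Adaptation runs during warm-up only: the scale moves multiplicatively toward
a 0.234 acceptance rate (the classic optimum for multivariate random-walk
MH), and C_i is an exponentially-weighted moving average (weight 0.02) of the
row's empirical covariance with a 10⁻⁸ PSD jitter, refreshed every 20
updates.  After warm-up all adaptation is frozen, so the retained chain is
Markov.  Warm-up defaults to half the iterations, thinning to 10.  One root
seed feeds a hyperparameter stream, a crossover stream and one stream per
experiment via `SeedSequence.spawn`, making chains bit-reproducible.  Initial
values are the prior means; a non-finite initial posterior raises with advice
to start from the prior mean.  The MAP estimate is the stored state with the
largest log-posterior (ties resolved toward the later draw).

## Synthetic data and what it shows

`generate_dataset` is the exact forward model of the statistical layer:
per-paper offsets, then factor rows, then simulated protocols, then
kind-specific noise added on the comparison scale of each experiment type
(IV records are generated capacitance-normalised, on the signed-square-root
scale).  Synthetic IV experiments use a 50 mM bath Na⁺ — a standard
experimental manoeuvre to limit current size — so the reversal potential
falls inside the voltage grid and the reversal QC is exercised.  The default
layout mirrors the curated study's structure (6 papers, 44 experiments across
the protocol kinds, temperatures 17–25 °C); the reduced layout (3 papers,
9 experiments, 8 free factors, compact grids) sizes the parameter-recovery
study for a single CPU: 10 seeds × 1200 iterations runs in a few minutes and
is the scale at which the coverage acceptance check operates.

What passing recovery shows: on data generated by the model's own assumptions
the sampler concentrates near the truth, credible intervals have roughly
nominal coverage, and the per-kind noise ordering is identified.  What it
does not show: robustness to digitisation error, non-Gaussian noise,
protocol mis-annotation, or model misspecification present in real curated
data — none of which the generator emulates.

## Population generation

Draws come from N(β₀ + β_T·(T − 17), Σ*) — UVEP offsets deliberately excluded
so the population represents the overall fit rather than any lab.  Σ* caps
the standard deviations of `mss_shift` and `tau_hf_shift` at 0.4 (factor
scale): the spread of IV-curve locations across sources inflates exactly
these two factors, and the cap rescales their rows/columns so every
correlation coefficient is preserved (congruence by a positive diagonal, so
positive definiteness survives).  The population temperature defaults to
body temperature (37 °C); 40 °C or any other value is a parameter, not a
code change.  Curve summaries report the pointwise population mean and std
together with the theoretical-mean curve (the protocol run at the
distribution mean).

## Tissue simulation

The channel is embedded behind a `HostCellAdapter` contract; the bundled
minimal host combines an inward-rectifier-like background K⁺ current (strong
below ≈ −60 mV), a slow delayed repolarising current (τ = 80 ms) and a small
background leak, resting near −80 mV with an atrial-like brief plateau.  The
validation quantities — maximum upstroke velocity and conduction velocity —
are dominated by I_Na and coupling, which is why a minimal host suffices;
users with a full atrial AP model can plug it into the same adapter.
Whole-cell use applies the standard corrections: h_ss/j_ss midpoints +16 mV,
activation/inactivation steady-state slopes widened by 1.6 mV (additive by
default; a multiplicative mode is available since the correction's algebra
is ambiguous), and a conductance scalar tuned by batched bisection until the
mean cell's dV/dt_max is within 2 % of a target.

Numerics: fixed-step integration with exact exponential updates for the
gates (the activation pair exactly; each 3-state chain by sequential
pairwise splitting, exact within each pair per substep) and forward Euler
for V; dt = 5–20 µs depending on the driver.  The fiber is a 100-cell 1-D
cable with nearest-neighbour coupling (default 15 ms⁻¹, no-flux ends,
stimulus into the first 5 cells), 100 µm cells.  Fiber upstroke is the mean
dV/dt_max over cells {20, 30, …, 80}; conduction velocity uses the
activation times (time of maximal dV/dt) of cells 30 and 80.  The default
coupling places CV in the atrial range; conduction block is reported as an
undefined CV with a reason, not an exception.

## Known limitations

- The crossover move is not an exactly balanced kernel (see above).
- The analytic back end assumes piecewise-constant command voltages; ramp
  protocols would need the BDF path.
- The minimal host is not a calcium-handling atrial myocyte model; absolute
  APD and plateau morphology are indicative only, and absolute upstroke/CV
  values depend on the host and coupling chosen.
- Late/persistent Na⁺ current and drug-block states are out of scope, as is
  temperature scaling inside the channel kinetics.
- With few papers the UVEP scales are weakly identified; their role is
  regularisation of inter-paper differences, and the recovery study sizes
  the uncertainty honestly rather than pinning them.
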