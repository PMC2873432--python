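# Methods

## The pool model

phyB dynamics are modelled as six pools under mass-action kinetics:
cytosolic, nucleoplasmic and nuclear-body (NB) bound phyB, each as the Pr
and Pfr conformer.  The system is linear and time-invariant within any
constant-light interval, `dx/dt = A x + b`, with the synthesis flux
`k_s = z·k_dr` as the only inhomogeneity.  Consequences used throughout:

* every pool, and every steady state, is proportional to the expression
  strength `z`, so all normalised observables are z-invariant;
* steady states come from solving the linear balance equations directly;
* the stiff integrator (`scipy.solve_ivp`, BDF, rtol 1e-8, atol 1e-10,
  analytic Jacobian) can be cross-checked against the exact piecewise
  matrix-exponential solution, which the test suite does with an
  independently hand-built rate matrix.

Assumptions: dimerisation is neglected; intracellular diffusion is fast
(well-mixed pools); nuclear import is Pfr-specific; dark reversion acts on
the diffuse cytosolic and nucleoplasmic Pfr but not on NB-bound Pfr (the
NB pool is a storage/protection compartment); all Pr pools degrade at
`k_dr`, all Pfr pools at `k_dfr`.  Photoconversion applies in all
compartments by default (`nuclear_photoconversion` flag), since far-red
pulses dissolve NBs in vivo, implying light reaches nuclear phyB.

Segment boundaries of a light program are hard integrator restarts, and
the boundary state is always evaluated exactly.  Integrator values in
[−1e-9, 0) are clamped to zero (the floor sits one order above the
absolute tolerance, which is what the solver can actually guarantee);
anything more negative raises.

### Rate-constant defaults (1/min unless noted)

| parameter | default | origin |
|---|---|---|
| k_3 (NB association) | 3.98 | multi-experiment fit estimate |
| k_4 (NB dissociation) | 1.51 | multi-experiment fit estimate |
| k_r (dark reversion) | 0.0321 | multi-experiment fit estimate |
| k_dr (Pr degradation) | 0.00061 | accumulation-transient estimate |
| k_dfr (Pfr degradation) | 0.0024 | multi-experiment fit estimate |
| k_in (nuclear import) | 1.0 | fixed; keeps cytosolic Pfr small (~3 % of total Pfr after a saturating pulse) |
| k_5 (NB-Pr decomposition) | 0.05 | fixed; depletes Pr-NBs on the ~1 h scale |
| σ_r + σ_fr | 0.1 per (µmol m⁻² s⁻¹) | chosen so a 5 min, 22 µmol m⁻² s⁻¹ red pulse is strongly saturating |
| red photoequilibrium σ_r/(σ_r+σ_fr) | 0.87 | classic phytochrome red-light value |
| far-red (RG9) photoequilibrium | 0.001 | long-wavelength far-red sets 99.9 % Pr |

`k_in`, `k_5` and the cross-section scale are not identifiable from the
modelled experiments and are fixed.  The two headline deterministic
outputs are insensitive to them: varying `k_in` five-fold moves the
full-model dark-reversion half-life between 63.4 and 68.6 min, varying
`k_5` five-fold or the cross-section scale two-fold leaves it at
68.4–68.6 min; the 24 h red-light degradation stays at 66.8–68.2 % under
the same variations.

With these defaults the model yields a full-model dark-reversion
half-life of ≈ 69 min (first-order reading at the same rate: 23 min) and
a 24 h degradation of ≈ 68 % at 3 µmol m⁻² s⁻¹ red light.

## The growth law

Dark growth uses the per-capita, time-rescaled logistic form

    dL/dt = Θ(t − t_growth) · L · (α(t) − βL) / (1 + γ(t − t_growth)),

whose closed-form dark solution is
`L(t) = (α₀/β) / (1 + (α₀/(βL₀) − 1)(1 + γτ)^(−α₀/γ))`, τ = t − t_growth.
This is the simplest form satisfying the four constraints the growth data
impose: exponential-type growth with instantaneous rate `α₀/(1+γτ)` at
β = 0 (linear exactly at α₀ = γ, sublinear below, superlinear above),
saturation at α₀/β, and initial per-capita rate α₀ − βL₀.  The growth
clock (the ageing factor) starts at initiation, not at germination.  The
form is pluggable (`GROWTH_FORMS`); an absolute-rate alternative
`dL/dt = (α − βL)/(1+γτ)` is available and integrated numerically.

Light enters through `α(t) = α₀/(1 + K′²ũ²(t))`; `1/K′` is the signal
level at half-maximal growth rate.  Because the protein pools equilibrate
hours before growth initiation, light-grown curves default to the
steady-signal coupling (closed form with a rescaled α₀); full
time-dependent coupling is available via `simulate_growth`.

The equilibrated end point `L′ = (α₀/β)/(1+K′²ū²)` is a t→∞ limit.
Under strong inhibition the effective α/γ ratio falls below 1 and the
approach to the asymptote becomes extremely slow, so finite-horizon
(four-day) relative lengths sit several percent above the algebraic
abundance-response ratio.  Tests compare the two with an explicit
finite-horizon margin rather than pretending four days is infinity.

Filter-paper setups limit growth differently from agar plates; β is
multiplied by a configurable `setup_beta_factor` (default 0.69, the
printed length ratio of the two setups; the alternative reading 0.57 can
be configured).  Only within-setup, normalised observables are used in
tests, where this scaling largely cancels.

### Growth-parameter defaults

The fitted ageing parameter reported for this system (γ ≈ 142/min with
α₀/γ = 5.66) cannot produce a multi-day S-curve under any reading of the
growth law — it saturates the curve within a minute of onset — so the
synthetic-data generator uses its own internally consistent set: the
fitted *ratio* α₀/γ = 5.66 is kept, γ = 5e-4/min places the curve's rise
on the observed multi-day scale, β = α₀/13.29 pins the agar dark
asymptote at 13.29 mm, seed length L₀ = 0.3 mm, growth initiation
t_growth = 2111 min, inhibition constant K′ = 6.87 (equal to the
dimensionless K, since concentrations are in wild-type units).  Fitted γ
values are treated as internally consistent with their own time
normalisation and are never asserted against curve shape.

## Virtual experiments

* **FRAP.**  After a 24 h red pretreatment (simulated explicitly from the
  etiolated state), a fraction of the NB-bound Pfr is instantaneously
  marked invisible.  Labelled and unlabelled molecules share all rates,
  so the visible copy obeys the same linear system; newly synthesised
  protein is visible.  The observable is the visible NB signal divided by
  the unperturbed NB trajectory (the acquisition/decay correction) and
  rescaled to its post-recovery plateau.  Recovery relaxes at ≈ k_3+k_4
  (half-time ≈ 0.13 min) to a plateau set by the nuclear mixing fraction.
* **Dark reversion.**  A 5 min, 22 µmol m⁻² s⁻¹ red pulse from the
  etiolated all-Pr state (simulated, not assumed to photoequilibrate),
  then darkness; the observable is total Pfr over total phyB, normalised
  to lights-off.  A single-exponential variant `exp(−k_r t)` models
  heterologous expression without NB formation.
* **Degradation.**  Continuous red light from the etiolated state; total
  phyB normalised to the dark level.
* **Accumulation.**  In darkness only synthesis and Pr degradation act,
  giving `Ptot(t) = z(1 − e^{−k_dr(t − t_syn)})` after the synthesis
  onset t_syn.
* **Fluence-rate response.**  Per fluence, the steady signal of the
  chosen submodel (photochemistry-only, +dark-reversion, or full) sets a
  constant growth rate; the read-out is day-4 length relative to dark.

The etiolated initial condition places all phyB as cytosolic Pr at level
z (import is Pfr-specific, so dark-synthesised phyB stays cytosolic);
a configurable split between cytosol and nucleus is supported through
custom initial states.

## Fitting

The merit function per experiment is `χ² = Σ((y_i − y(t_i,p))/SE_i)²`;
the overall objective is the plain unweighted sum over experiments,
minimised by bounded trust-region least squares (`scipy least_squares`,
TRF) with rate-like parameters on log10 scale.  Multistarts (user-set
count) draw log-uniformly inside the bounds from a seeded generator; the
best converged start wins, and identical seed and configuration reproduce
the result bitwise.  Zero standard errors (noise-free synthetic data) are
replaced by unit weights so exact data remain fittable.  Per-point
empirical SEs from very few replicates are poor χ² weights;
`with_pooled_se` substitutes the pooled RMS value, the standard
stabilisation for homoscedastic noise, and is used in the onset-recovery
analyses.

Confidence intervals: linearised 95 % intervals from the Jacobian
covariance at the optimum (computed on the internal log scale and
back-transformed; the delta method provides linear-scale standard
errors).  With measured SEs the covariance is `(JᵀJ)⁻¹` directly; if the
fit ran entirely on unit weights the unknown-variance convention applies
and the covariance is scaled by the reduced χ², so intervals collapse
together with the residuals on noise-free data.  Profile-likelihood
intervals (χ²_min + 3.84 crossing, re-optimising the remaining
parameters) are the rigorous option.  On 200 seeded replicates of the
accumulation fit the linearised intervals cover the generating onset and
abundance ~93–95 % of the time.

Model selection uses the Gaussian-residual convention AIC = χ² + 2k,
BIC = χ² + k·ln n on fits of identical data.

### Growth-curve alignment

Per seedling, the hourly trace is smoothed (5-point centred moving
average, then isotonic regression — growth is monotone) and the 0.5 mm
crossing is located by linear interpolation; a local hinge (changepoint)
least-squares fit on the raw points in a (−720, +480) min window then
refines the crossing.  The refinement matters: interpolation on a
monotone-smoothed noisy baseline is biased ~30 min early (baseline noise
inflates the isotonic staircase), while the hinge estimate is unbiased to
within a few minutes at the study noise level.  Curves are shifted so
crossings sit at time zero, interpolated to a shared hourly grid, and
averaged pointwise with standard errors; the mean crossing time is the
growth-initiation estimate.

## Synthetic data

The generator evaluates the virtual experiments at ground truth (the
fitted rates above) and adds independent Gaussian noise per biological
replicate, reporting replicate means ± SE.  Study conditions baked into
the defaults: 13 seedlings, hourly imaging over six days, growth
initiation 2111 min with 180 min between-seedling SD; five averaged FRAP
traces (σ = 0.05); dark-reversion spectroscopy at 9 time points to 24 h
(σ = 0.05, 4 replicates); degradation blots at 0/1/6/12/24 h (σ = 0.1,
4 replicates); dark accumulation on a 3.8× over-expressing line sampled
every 2 h from 12 h to four days (σ = 0.1, 3 replicates) — a design dense
enough that the 648 min onset is recoverable to the required few-percent
precision; lengths carry 0.3 mm measurement noise.  Each dataset kind
draws from its own child stream of the master seed, so changing one
kind's replicate count never perturbs another kind's draws.

The seedling generator defines its ground-truth `t_growth` exactly as the
measurement procedure does — the time the hypocotyl reaches 0.5 mm — by
placing the latent growth onset at `t_cross − δ`, with δ the
deterministic time to grow from seed length to the threshold.  Defining
it as the latent ODE onset instead would build a ~195 min systematic
offset into every recovery, an artefact of the arbitrary seed-length
choice rather than a property of the procedure.

What the generator does *not* emulate: replicate-to-replicate variance
structure beyond i.i.d. Gaussian noise (no per-blot scaling errors, no
correlated drift), circadian growth modulation, per-seedling variation in
anything but initiation time, and image-level artefacts.  Passing
recovery tests therefore demonstrate estimator correctness and
identifiability under the stated noise model, not robustness to every
failure mode of the original assays.

## Numerical and design notes

* The mean initiation time of a 13-seedling panel has an irreducible
  sampling SD of 180/√13 ≈ 50 min; recovery of the 2111 min ground truth
  is accurate to roughly that scale by construction, and the alignment
  estimator adds ≈ 28 min RMS on top.
* With the reconstructed cross-sections the sensitivity scan leaves k_5,
  k_r and k_in essentially flat (< 6 % over 0.1–10×) at saturating red;
  k_1 and k_2 retain a mild residual effect (< 2.1× across the band,
  versus > 10× for the abundance-class parameters z, k_dfr, α₀/β and K),
  because rescaling one cross-section shifts the photoequilibrium
  itself.  A cross-section pair whose photoequilibrium effect saturates
  harder would flatten them completely.
* Dark-reversion and FRAP observables are independent of z; the
  spectroscopy line's expression strength is therefore irrelevant and
  defaults to 1.
* Ties and degenerate inputs: dark segments require zero fluence and vice
  versa; only the final light-program segment may be open-ended; the
  half-life utility demands a curve starting at its maximum and raises if
  it never halves; alignment excludes (with a warning) seedlings that
  never reach the threshold.
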