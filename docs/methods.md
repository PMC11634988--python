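# Methods

## Models

### qPCR: two-step (hurdle) model

Each well is a Bernoulli detection event followed, conditionally on
detection, by a Normal cycle-threshold observation:

* Z ~ Bernoulli(θ), logit(θ) = φ0 + φ1·log10 C — detection probability
  rises with concentration (φ1 > 0 enforced).
* Y | Z=1 ~ Normal(μ, σ), μ = β0 + β1·log10 C — the standard-curve line;
  β1 = −1/log10 2 ≈ −3.32 at 100% amplification efficiency (β1 < 0
  enforced).
* σ = exp(γ0 + γ1·log10 C) — Ct scatter is log-linear in concentration;
  γ1 < 0 captures the empirical pattern that quantification variability
  grows as template becomes scarce.

Standards enter with their nominal log10 C; each unknown sample carries
one latent log10 C shared by its technical replicates, so the posterior
pools replicate information and a fully non-amplified sample is still
informed (downward) by the detection layer.  One shared (φ, β, γ) set is
used for standards and environmental samples alike.  Detected Ct values
are modelled as exact Normal draws with no truncation term at the cycle
cap; plates' differing cycle limits act only through the binary outcome.

`continuous_only` mode drops the φ layer and all non-detected wells.  A
sample with no detected replicate then has no likelihood contribution:
its estimate reproduces the latent prior and is flagged `prior_driven`.

### ddPCR: binomial/cloglog model

W ~ Binomial(U, ω) positive droplets out of U, with
cloglog(ω) = κ0 + κ1·log10 C.  This is the Poisson partitioning law
(occupancy 1 − exp(−C·V)) written as a generalised linear model, so the
calibration line is estimable from standards instead of assumed: at 100%
efficiency κ0 = ln V (V = droplet volume, nominally 0.00085 μL) and
κ1 = ln 10.  Departures are diagnostic — `exp(κ0)` is the implied
droplet volume and `κ1/ln 10` the assay efficiency.  Replicates share a
latent log10 C exactly as in the qPCR model.  The single-well maximum
likelihood estimate with κ fixed at (ln V, ln 10) coincides with the
vendor Poisson formula C = −ln(1 − W/U)/V, which is verified in the test
suite; the Bayesian fit differs by pooling replicates and propagating
standard-curve uncertainty.

Saturated wells (W = U, infinite point estimate) are excluded from the
likelihood with a warning rather than fitted; the cloglog likelihood
would remain finite but a saturated well carries almost no concentration
information beyond a lower bound, and flagging keeps the behaviour
visible.  A sample whose only wells are saturated therefore drops out of
the fit entirely.

### Limits of detection and quantification

Closed forms, not fitted quantities.  qPCR: one copy in the pooled
replicate volume, C_lt = 1/(n·V_rxn) = 0.05/n copies/μL at 20 μL.
ddPCR: one positive droplet among the pooled droplets,
ln C_lt = cloglog(1/(nU)) − ln V, and an upper limit at one remaining
negative droplet, ln C_ut = cloglog((U−1)/U) − ln V.  The upper-limit
argument is read as (U−1)/U — all but one droplet positive; the
degenerate case U = 2 makes the two limits coincide.  Replicates pool by
multiplying the droplet total (each droplet is an independent end-point
reaction), so both platforms' lower limits scale as 1/n.

## Priors

The model papers this package follows state no priors, so weakly
informative choices centred on PCR physics are used:

| parameter | prior | rationale |
|---|---|---|
| φ0 | Normal(0, 5) | vague on the detection intercept |
| φ1 | Normal(1, 2), > 0 | detection must rise with concentration |
| β0 | Normal(40, 10) | typical qPCR intercepts 35–45 cycles |
| β1 | Normal(−3.32, 2), < 0 | centred on perfect dilution slope |
| γ0 | Normal(0, 2) | Ct SD scale free over e^±4 |
| γ1 | Normal(0, 1) | allows strong SD–concentration coupling |
| κ0 | Normal(ln 0.00085, 1) | centred on the manufacturer droplet volume |
| κ1 | Normal(ln 10, 0.5), > 0 | centred on 100% efficiency, wide enough to flag anomalies |
| log10 C (unknowns) | Normal(0, 3) | covers 10⁻⁶–10⁶ copies/μL |

## Inference

Affine-invariant ensemble MCMC (emcee) with a mixture of
differential-evolution (80%) and snooker (20%) moves, which mix markedly
better than the stretch move once the latent concentrations push the
dimension past ~20.  The log-posterior is vectorised across walkers, so
one fit costs a few thousand small numpy broadcasts.  Walkers are
initialised at a data-driven warm start (least-squares standard-curve
fit; per-sample inversions for latents) with small jitter.

Walkers are reported as chains; the default budget (max(32, 2·ndim+2)
walkers × 3,500 post-warmup draws after 2,000 warm-up iterations)
satisfies the ≥4 chains × ≥1,000 draws contract with margin.  Rank-based
rhat and bulk ESS are computed per parameter (arviz); the `converged`
flag requires max rhat < 1.05 and min ESS ≥ 400 and is reported, never
silently enforced.  All randomness flows from a single integer seed, and
a fixed seed reproduces draws bitwise.

Numerical notes: the binomial likelihood clips the linear predictor to
[−690, 50] before exponentiating so that log ω stays finite for any
walker excursion; Bernoulli terms use the log-sum-exp form of
log-sigmoid; the Ct layer clips log σ to ±20.  Estimates are empirical
2.5/50/97.5% quantiles of the latent draws; the non-detect rule is
median concentration < 10⁻³ copies/μL with the boundary counting as a
detect.

## Synthetic plates

The generator draws from exactly the generative structure the fitters
assume, plus two instrument realisms: droplet totals scatter around
20,000 (Normal, CV 5%, floored at 1,000), and qPCR Ct draws falling
outside (0, max_cycles] are censored to non-detects.  Default truth:
φ = (1.5, 2.2), β = (38, −3.32), γ = (−1.2, −0.25),
κ = (ln 0.00085, ln 10).  Standards span 10⁻¹–10⁶ copies/μL (qPCR) or
10⁻³–10⁴ (ddPCR) in decade steps, in triplicate; 30 unknowns draw
log10 C from Normal(−1, 1.5) — the low-concentration regime typical of
eDNA — plus 5 truly absent samples and 2 no-template controls that can
never amplify.  Controls are read and stored but excluded from fits
unless explicitly included.

What the generator does **not** emulate: PCR inhibition, pipetting error
in the dilution series, between-assay droplet-volume differences,
contamination, or multi-plate batch effects.  Passing recovery tests
therefore demonstrate correctness of the inference under the model's own
assumptions, not robustness to the ways real plates violate them.

## Experiments and problem sizes

Recovery and comparison experiments use one plate of 8 standards × 3
replicates plus 20 unknowns × 3 replicates, replicated over 20
independent seeds — a size chosen to mirror a single realistic run while
keeping a full experiment batch in the minutes range.  Recovery
experiments use a 52-cycle assay so the Ct layer is never censored and
the fitted model matches the generator exactly, and draw the unknown
truths from the fitters' latent prior Normal(0, 3) rather than the
field-like Normal(−1, 1.5): credible-interval coverage is only a
calibrated check when the simulated truth comes from the prior the model
actually uses; conditional coverage of Bayesian intervals is not
guaranteed when the latent prior and the generating distribution
disagree, a caveat that applies equally to interpreting credible
intervals on real plates.  Matched-precision
experiments simulate qPCR and ddPCR plates sharing identical latent
truths (16 samples from Normal(−1, 1.5) plus three at 10⁴ copies/μL to
probe the high-concentration regime where the two qPCR variants must
agree).

Grid-posterior oracles evaluate likelihood × prior for a single latent
on a 2,000-point grid over [−12, 12] and compare the MCMC draws by total
variation over equal-probability bins of the oracle distribution.

## Design choices and known limitations

* **Sampler family.** An ensemble sampler was chosen over
  gradient-based HMC: the posteriors are low-dimensional enough
  (≤ ~80) that DE-move ensembles converge in seconds, and the
  likelihoods stay free of gradient plumbing.
* **Borderline non-detects under the two-step qPCR model.** With the
  default priors and detection strength, a sample whose three replicates
  all fail to amplify has posterior median ≈ 10⁻²·⁹ copies/μL — just
  above the 10⁻³ non-detect threshold.  The classification of fully
  negative qPCR samples is therefore sensitive to the latent prior and
  to the fitted detection curve (stronger detection pushes blanks
  further down); ddPCR blanks land well below threshold because a zero
  droplet count among ~60,000 is far stronger evidence of absence.
* **Cycle-cap harmonisation.** Plates with different cycle caps are
  comparable only through the detection outcome; no truncation
  correction is applied to detected Ct values near the cap.
* **The x·log(x) slope alternative** occasionally suggested for
  low-concentration ddPCR calibration lacks a defining equation and is
  not implemented.
* **Concentration units** are copies/μL of reaction volume throughout;
  conversion to template-extract or filtered-water volumes is the
  user's responsibility.
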