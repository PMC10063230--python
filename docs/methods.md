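# Methods

This note records the model, the numerical choices, and the reasoning
behind design decisions that were genuinely open, in the spirit of the
methods documentation of simulation packages. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Whole-brain Hopf model

Each region is the normal form of a supercritical Hopf bifurcation in
Cartesian coordinates (state z_j = x_j + i·y_j), diffusively coupled
through the structural connectome K and driven by additive Gaussian noise.
Parameters and units:

| parameter | meaning | default | unit |
|---|---|---|---|
| a_j | local bifurcation parameter (excitation/inhibition proxy) | fitted; 0 at the bifurcation | — |
| ω_j | natural angular frequency | estimated from the 0.04–0.07 Hz band | rad/s |
| G | global coupling gain | 0.5 after the grid stage | — |
| β | noise amplitude | 0.04 | — |
| dt | Euler–Maruyama step | 0.1 | s |
| duration / transient | simulated time / discarded head | 480 / 20 | s |

Conventions chosen where the mathematics leaves room:

- **Noise.** η_j(t) enters both component equations as independent
  Gaussian increments per region and component, scaled β·√dt (the standard
  Euler–Maruyama treatment of additive noise).
- **Initial state.** Independent uniform components in [−0.1, 0.1],
  seeded: a small perturbation off the fixed point.
- **Connectome scaling.** Applied once at load: symmetrize, zero the
  diagonal (self-coupling cancels in the diffusive form anyway), rescale
  to a maximum weight of 0.2 (weak-coupling condition).
- **Forcing.** The periodic drive F₀·cos(ω₀t + φ) is added to the x-drift
  only, in phase at both members of the stimulated homotopic pair; a flag
  can also force y. Each member is driven at its own natural frequency.
- **Integration accuracy.** Explicit Euler carries a known limit-cycle
  radius bias: the per-step magnitude fixed point sits at
  r² ≈ a + dt·ω²/2, i.e. +2.7% at a = 0.09, ω = 2π·0.05, dt = 0.1.
  This is immaterial for the noisy near-bifurcation regime the model is
  fitted in, but noiseless accuracy checks in the test suite run at
  dt = 0.02, where the radius error is ~0.5% and the dt-halving
  sensitivity is below 1%.
- Divergence is detected by an explicit finiteness check every 50 steps
  and reported with the offending step and region.

## Functional connectivity and the fit objective

Simulated x-components are decimated to one sample per 2 s (plain stride;
the band-pass that follows removes out-of-band content), linearly
detrended, band-passed 0.04–0.07 Hz with a zero-phase 2nd-order
Butterworth filter (the de-facto standard for this band), z-scored, and
correlated (Pearson). Group averages apply Fisher's r-to-z before the
mean. FC matrices are compared with SSIM over a fixed dynamic range of 2
(entries span [−1, 1]) with the canonical constants K1 = 0.01, K2 = 0.03.

Two SSIM variants are provided:

- `global`: one SSIM statistic from whole-matrix means, variances and
  covariance; cheap and smooth.
- `windowed`: the canonical mean of local Gaussian-weighted (σ = 1.5)
  SSIM values, numerically identical (≤ 1e-6, verified against
  scikit-image) to the standard reference implementation.

**The fitting objective uses the windowed form.** The global statistic
compresses each matrix to three numbers, which a six-parameter search can
overfit: during development the genetic algorithm routinely found wrong
parameter patterns with *better* global-SSIM fit than the ground truth.
The windowed form retains local structure and removed that failure mode.
`ssim_similarity` itself defaults to `global` for cheap scoring and
reporting; the fit distance is always 1 − SSIM, minimized.

## Fitting

Stage 1 scans homogeneous (a, G) on a grid (canonically 100×100 over
[−0.2, 0.2] × [0, 3]), averaging the fit distance over independent runs
per cell. In the synthetic worlds the landscape shows a sharp valley in
`a` and a shallow valley in `G` (coupling trades off against the
bifurcation parameter), so the recovered `a` is reliable to one grid cell
while cells along the G valley floor can be statistically
indistinguishable at modest run counts — the self-consistency test asserts
exactly that geometry. Stage 2 fixes G = 0.5 and optimizes the six group
coefficients Δ with a genetic algorithm:

- population 10, offspring exactly 20% elite copies, 60% uniform per-gene
  crossover of fitness-proportionally selected parents, 20% single-gene
  Gaussian mutants (σ = 0.02 default; larger values suit reduced
  generation budgets);
- initialization uniform in [−0.02, 0.02] ("close to zero"); Δ clipped to
  [−0.3, 0.3] so per-region parameters stay in a dynamically sensible
  range bracketing the grid interval;
- selection score = max(GoF) − GoF + 1e-9 (lower distance → higher
  score), roulette sampling;
- halting: generation limit (200), best-ever unchanged within 1e-6 for 50
  generations, or mean population GoF changing less than 1e-6 over 50
  generations. The mean criterion is read as *change in* mean below
  threshold: a literal absolute mean below 1e-6 is unreachable for a
  distance with a sampling-noise floor.
- **Evaluation seeds.** By default every evaluation inside one GA run uses
  a single frozen simulation seed (common random numbers). With fresh
  seeds per evaluation, the best-ever record is a running minimum over
  noisy draws and systematically selects lucky simulations rather than
  good parameters (a winner's curse we observed directly); freezing the
  seed makes the objective a deterministic surface. Per-evaluation seeds
  remain available (`eval_seed_policy="per_eval"`). Independent runs of
  `fit_group` use different frozen seeds, so ensembles still average over
  the realization-specific bias.

### Identifiability at desk scale

A single 240-s narrowband FC estimate has only ~13 effective temporal
degrees of freedom per entry. At 20 regions (190 distinct FC entries) that
is not enough information for a six-parameter fit from one simulation per
evaluation: the realized objective has spurious minima below the ground
truth's own value, and no optimizer can beat that ceiling (we verified
this with frozen-seed surfaces, averaged evaluations, and
population-consensus readouts). At the full 90-region scale (4005
entries) the same reduced-budget protocol recovers the ground-truth
per-region pattern with correlation ≈ 0.9 in most runs. The test suite
therefore contains both: a desk-scale recovery test at a strict bar
(r ≥ 0.8 in 8 of 10 runs, which documents the desk-scale ceiling) and a
full-scale recovery test that passes.

## Variational autoencoder

Encoder 512 → 64 (ReLU) → 2-D diagonal-Gaussian latent; decoder mirrored;
input is the upper-triangle vector of the FC matrix (halving the
dimensionality and avoiding duplicated symmetric entries). Loss =
per-sample summed squared reconstruction error + kl_weight (default 1,
standard ELBO) × KL(posterior ‖ N(0, I)); Adam at 1e-3, batches of 128,
50 epochs, seeded 80/20 train/validation split. The implementation is
self-contained numpy (hand-written backprop), which keeps training
bit-reproducible for a given seed. Encoding returns the posterior mean so
trajectories are deterministic; decoding devectorizes, symmetrizes, clips
to [−1, 1] and restores the unit diagonal. Log-variances are clipped to
±15 for numerical safety.

## Stimulation and landscapes

Sync/Noise shift the bifurcation parameters of both members of one
homotopic pair by Δa (positive toward synchronized oscillation, negative
toward noisy fixed-point dynamics); Wave adds in-phase periodic forcing at
each member's own natural frequency. Intensities sweep 0 → 2 (0 → −2 for
Noise) in steps of 0.1, with 100 independent simulations per grid point at
full scale; per-intensity FC uses Fisher-z averaging for consistency with
group FC. Pairs are ranked by the minimum latent distance of their
trajectory to the target point; the reported top decile contains
ceil(n_pairs/10) pairs, both member regions of each.

Homotopic pairing defaults to consecutive (even, odd) indices per the
AAL left/right interleaving convention and can be overridden explicitly.

For landscape work the VAE is best trained on run-averaged FC samples
(matching what the sweep encodes): training on single-run matrices lets
within-condition sampling noise dominate the two latent dimensions, while
averaged samples make the between-condition axis principal. The lesion
test and the acceptance script train on 10-run averages for this reason.

## Synthetic study conditions

The generator emulates the study's inputs with known ground truth; it is
a pure function of (spec, seed). Defaults, chosen once as realistic for
the data class they emulate:

- **Connectome**: homotopic pairs assigned jointly to 4 contiguous
  modules; between-module weights 5% of within-module, multiplicative
  lognormal noise (σ = 0.5), homotopic entries boosted above the
  within-module level, rescaled to max 0.2. Empirical streamline-count
  matrices are heavy-tailed and dominated by within-module and homotopic
  connections; a dense background (an early draft used 30%) produces a
  uniformly driven regime in which local parameters leave no imprint on
  FC.
- **Frequencies**: uniform in 0.04–0.07 Hz, shared within a homotopic
  pair (mirrored anatomy). Without sharing, strongly oscillating partners
  at different frequencies fail to phase-lock at these coupling strengths
  and their regime becomes invisible to FC.
- **Metadata**: mirrored centroids, pair-wise round-robin network labels
  (six networks, bilateral, balanced), atrophy as a smooth Gaussian bump
  plus noise.
- **Groups**: CNT at the bifurcation (Δ* = 0); AD-like mild/severe with
  the first network shifted −0.10/−0.20 toward fixed-point dynamics; a
  bvFTD-like group with the second network shifted +0.15 toward the
  synchronized regime. Ten subjects per group, 480 s scans at full
  emulation (240 s for desk-scale tests), one independent simulation per
  subject. These are fixtures with known structure, not claims about
  biology.

What the generator does **not** emulate: hemodynamics, head motion,
scanner noise, multi-site effects, subject-level anatomical variability
(all subjects share one connectome). Passing tests therefore demonstrate
internal consistency of the method — recovery of known ground truth under
the model's own assumptions — not performance on real data.

## Reporting

Group comparisons use Cohen's d only (pooled SD with (n−1) weights;
Hedges' correction behind a flag); d > 0.8 is flagged large, d > 1.3 very
large, with the direction of shift (toward fixed point vs toward
oscillation) reported alongside. No p-values are emitted: significance
against a simulated null can be inflated arbitrarily by running more
realizations. Median splits by a severity scalar send ties to the upper
subgroup.

The pipeline driver chains synth → fit → vae → perturb → report from one
YAML config, derives every stage seed from the config seed, and writes a
manifest with per-stage status and SHA-256 hashes of all artifacts;
completed stages are skipped on rerun in the same directory.

## Known limitations

- The desk-scale identifiability ceiling described above: 20-region,
  single-simulation fitting is noise-limited by construction.
- The (a, G) grid landscape is degenerate along a coupling valley; only
  `a` is sharply identified in the synthetic worlds.
- The VAE latent is two-dimensional by design; conditions whose FC
  signatures are orthogonal to the two principal axes of the training set
  are invisible in the landscape.
- Euler–Maruyama at dt = 0.1 s has the documented small supercritical
  radius bias; fits near the bifurcation are unaffected.
- Stimulation is single-pair and bilateral only; electric-field modelling
  of real stimulation montages is out of scope.
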