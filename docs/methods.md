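# Methods

## Model

The distribution of fitness effects (DFE) for new selected (nonsynonymous)
mutations combines a gamma-distributed deleterious component with a
discrete beneficial class.  Scaled effects are γ = 2·N_e·s with s the
selection coefficient of the mutant homozygote; dominance is h = ½
throughout, so all diffusion results are the genic-selection forms written
on the homozygote scale.  Defaults follow the classic strong-purifying
regime for coding sequence: shape β = 0.3, mean deleterious effect
γ_d = −2000, with the beneficial parameters (γ_a, p_a) varied by
experiment.  The deleterious gamma is parameterised by (shape, mean), the
form in which empirical estimates are reported, and is not truncated at
lethality: the fixation-rate and sojourn integrands vanish so fast in |γ|
that a truncation would be invisible in every quantity computed here, and
the forward simulator floors genotype fitness at zero.

Two synthetic-data generators share this DFE:

1. **PRF sampler** (`prf_core.sample_poisson_usfs`).  Each uSFS entry is an
   independent Poisson draw around the diffusion expectation
   θL·∫ Binom(i; 2n, x) τ(x; γ) dx averaged over the DFE, with
   τ(x; γ) = (1 − e^{−γ(1−x)}) / [x(1−x)(1 − e^{−γ})].  With divergence,
   the two substitution counts are Poisson around
   δ·L·E_DFE[r(γ)] (r(γ) = γ/(1 − e^{−γ})) plus the expected number of
   derived alleles fixed in the sample (see "sample-fixed alleles" below).
   This generator reproduces the inference model's own sampling noise
   exactly and carries no linkage; it is the right tool for studying the
   likelihood itself (power, bias, ridges) at full-study site counts
   (14 Mbp selected / 7 Mbp neutral) in milliseconds per dataset.

2. **Forward Wright–Fisher simulator** (`wf_forward`).  Diploid population,
   multinomial reproduction weighted by multiplicative fitness
   (1, 1 + hs, 1 + s per site, floored at 0), Poisson crossovers
   (r per bp per meiosis), Poisson mutation over a seven-gene chromosome:
   genes of five 300-bp exons separated by 100-bp neutral introns, each
   gene followed by 8,100 bp of neutral spacer (70,000 bp in total).  Each
   exonic mutation is independently selected with probability 2/3
   (nonsynonymous, effect from the DFE) and synonymous otherwise, so the
   effective site counts are L_sel = 7,000 and L_neut = 3,500 per
   replicate.  Introns and spacers are simulated because they mediate
   linked selection but are excluded from the analysis uSFS.  Mutation is
   infinite-sites within finite coordinates: a mutation landing on a
   segregating position redraws among the free positions of the same site
   class, keeping derived-allele polarization exact.  At full scale the
   design is N = 10,000, μ = r = 2.5 × 10⁻⁷ (θ = ρ = 0.01), 85,000
   generations of burn-in and a 200,000-generation divergence window
   (neutral divergence μT = 0.05).

### Rescaling

`rescale_config(cfg, Q)` simulates N/Q diploids with μ, r multiplied by Q
and all phase lengths divided by Q.  Because effects are stored as scaled
γ = 2Ns, every compound parameter (θ, ρ, γ, T/N) is invariant.  The
desk-scale profile used by the tests and the acceptance script is Q = 20–40
with burn-ins of 8–10 N′ generations; rescaling exaggerates per-site s
(mean deleterious s′ = −2 at Q = 20), which the fitness floor absorbs, and
is the standard trade-off of rescaled forward simulation: diffusion-scale
quantities are preserved while strong-selection discreteness effects grow.

### Sample-fixed alleles

The uSFS vector holds only the 2n − 1 polymorphic classes.  Derived alleles
fixed in the sample (population-polymorphic, sample frequency 2n) cannot be
distinguished from substitutions by the observer, so when divergence is
modelled they are pooled with the substitution counts — in the forward
sampler, in the PRF generator, and in the likelihood's expected divergence,
which adds θL·∫ x^{2n} τ(x; γ) dx to δL·E[r].  Without divergence they are
dropped.  Keeping generator and likelihood consistent here is what makes
the PRF datasets exactly self-consistent for the fitting stage.

## Likelihood and fitting

The likelihood is independent-Poisson over neutral entries (mean θL_neut/i),
selected entries (DFE-averaged expectation) and, with divergence, the two
substitution counts.  Free parameters: θ, β, γ_d (and δ with divergence),
plus (p_a, γ_a) in the full model; the null fixes p_a = 0 and has two fewer
parameters.  No bin-wise distortion (r_i) or polarization-error (ε)
nuisances are fitted: the synthetic data are undistorted and perfectly
polarized, and omitting them isolates the identifiability of the
positive-selection parameters.  A consequence worth stating explicitly is
that this likelihood extracts **more** information from divergence than
nuisance-laden fits of the same data would, so significance proportions in
weak-signal regimes sit above those reported by analyses that fit
distortion nuisances or whose optimizers frequently fail to converge.

Optimization is L-BFGS-B on transformed scales (log θ, log β, log |γ_d|,
logit p_a, log γ_a, log δ), from a data-driven initialization: θ from the
neutral-SFS maximum-likelihood value under the 1/i law, (β, γ_d) from a
coarse deterministic profile over a 6 × 6 grid against the observed
selected uSFS, p_a = 0.005 and γ_a = 10 as mild beneficial starts, δ from
the neutral substitution count.  `n_starts` (default 5) jitters the start
multiplicatively (factor ≈ 2) on the transformed scale; the best start by
log-likelihood wins, ties broken by lower gradient norm.  Convergence is
reported as finite-difference gradient max-norm < 0.01 on the transformed
scale; invalid parameter regions return a large finite penalty (10¹²)
rather than raising.

The likelihood-ratio test refers 2ΔlnL to χ² with 2 df.  Because the null
lies on the p_a = 0 boundary, this reference is conservative (the true
large-sample null is a mixture with mass at 0); the plain 2-df reference is
used deliberately, as the field's standard procedure.  Akaike weights
w ∝ exp(−ΔAIC/2) average the null and full fits, the null contributing 0 to
p_a, γ_a and α_DFE.  Likelihood surfaces re-optimize the nuisance
parameters at each (γ_a, p_a) grid point, warm-starting from the
neighbouring cell; failed cells record NaN.

## Numerical choices

- **Sojourn density**: evaluated with `expm1` for γ > 0 and in log space
  (log(−expm1(−t))) for γ < 0; |γ| < 10⁻¹² falls back to the neutral 1/x.
  Stable beyond |γ| = 10⁴.
- **Frequency integral**: composite Gauss–Legendre panels with breakpoints
  geometrically refined toward both endpoints (10⁻⁴ … 1 − 10⁻⁴), ≥ 22
  nodes per panel so the neutral integrand (a degree-2n−1 polynomial) is
  integrated essentially exactly — the neutral 1/i law holds to < 10⁻⁸
  relative error — while sojourn densities concentrated within ~10⁻⁵ of
  either endpoint (|γ| ~ 10⁴–10⁵ from the deleterious tail) remain
  resolved.
- **DFE average**: the deleterious integral substitutes the gamma quantile
  function, g = Q(u), and integrates over u ∈ (0, 1) — this removes the
  density singularity at 0 for β < 1 and the unbounded tail in one stroke.
  The public expectation (`dfe_expectation`, used by α_DFE and expected
  divergence) uses adaptive quadrature; the likelihood hot path uses a
  fixed panelled u-grid (70 nodes) so the objective is a smooth
  deterministic function of (β, γ_d), with per-shape quantile caching.
  The two routes agree to ~10⁻⁶ relative and are cross-checked in the
  tests.
- **Fixation rate**: r(γ) = γ/(−expm1(−γ)) for γ > 0 and
  γ·e^γ/expm1(γ) for γ < 0; no overflow at any float input, graceful
  underflow to 0 for strongly deleterious effects.
- **Forward simulator**: variant columns are kept position-sorted and
  purged of fixed/lost alleles every 4 generations (between purges, lost
  columns are all-False and fixed all-True, which affects neither relative
  fitness nor inheritance); single-crossover gametes — the overwhelming
  majority at ρ·L ≈ 0.35 per meiosis — are contiguous slice swaps in the
  sorted region.  Lethal genotypes (floored fitness) contribute a −10⁴
  log-fitness penalty per lethal site so the least-loaded individuals are
  still preferred when every individual carries one.

## What the generators do and do not emulate

The PRF sampler is the inference model's own data: results obtained with it
(power, coverage, ridge geometry) are statements about the likelihood under
correct specification, free of linkage.  The forward simulator adds the
linked-selection reality — background selection and sweeps depress
synonymous diversity (π_S/π_0 < 1) and induce genealogical correlation that
the PRF model ignores — but at desk scale its replicate counts are far
below the original 2,000-replicate study, so forward-based quantities are
order/consistency checks (π-ratio ordering across sweep regimes, α_Obs vs
α_DFE agreement), not precision reproductions.  Neither generator models
demographic change, population structure, ancestral-state error or
untranslated regions.

## Problem sizes

Inference experiments run the PRF generator at full-study site counts with
100 datasets per grid cell.  Forward runs use Q = 20 (N′ = 500, 10
replicates, burn-in 3,000 = 6N′, window 1,500 generations) for the strong
positive-selection α check and Q = 40 (N′ = 250, 4–6 replicates) for the
diversity-ordering and α-consistency checks; these sizes were chosen so a
complete analysis runs on one workstation CPU in minutes while keeping
Monte-Carlo error well below the effect sizes being asserted.

## Known limitations

- With-divergence significance proportions in the weakest cell
  (γ_a = 10, p_a = 10⁻⁴) are ≈ 0.12 here versus 0.02 in nuisance-laden
  reference analyses: the divergence excess contributed by rare strong
  beneficials (~700 substitutions on a ~49,000 deleterious baseline at
  these settings) is genuine signal (≈ 3σ), and a correctly-specified,
  well-converged likelihood partially detects it.  Fits that also estimate
  bin-distortion nuisances, or bootstrap replicates of a single simulated
  genome (whose test outcomes are strongly correlated), report lower
  proportions.
- The χ²₂ reference makes the LRT conservative under the exact null; no
  boundary-corrected mixture is offered.
- Gradient convergence (< 0.01) is rarely achieved in with-divergence fits
  even at the optimum's numerical neighbourhood — the transformed-scale
  curvature is extreme when divergence counts are in the millions — which
  mirrors the behaviour long observed for this model class; estimates and
  tests are unaffected (restarts and tightened tolerances leave them
  unchanged to < 10⁻³ log-units).
- The forward simulator's rescaling (Q ≥ 20) makes mean deleterious
  homozygotes lethal; this is inherent to rescaled strong-selection
  simulation, not a property of the full-scale design.
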