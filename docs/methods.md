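# Methods

## Generative model

Somatic single-base substitutions in a cohort are modeled as draws from K
latent mutational processes. Sample *n* has exposures
π_n ~ Dirichlet(α); each mutation picks a process z ~ Cat(π_n) and then a
(bin, type) pair from that process's topography

    p(b, m | z=k, θ) ∝ t_bm · exp( f_k(X_b) + g_km(X_b) ),

normalized over all bins and the 192 stranded trinucleotide-substitution
types. Availability-zero cells carry probability exactly 0 (never an
epsilon): a type that cannot occur in a bin must not absorb likelihood.

**Mutation types.** 6 pyrimidine-centered substitution classes × 16 flanks
× 2 strand orientations. Orientation 0 = reference strand carries the
pyrimidine. Collapsing orientations gives the conventional 96-channel
spectrum; the collapse is a defined projection, not the native
representation, because strand-asymmetric processes (transcription- and
replication-coupled) are first-class here.

**Bins.** The genome is partitioned at every discrete-feature state change
plus a fixed-width grid (default `interval_bp = 10_000`), yielding segments
of constant discrete state. Within one grid window, segments with an
identical discrete state are re-merged into a single (possibly
non-contiguous) bin — e.g. the two flanks a gene carves out of a window.
The window index is part of bin identity; merging identical states
genome-wide would average continuous macro features over the whole genome
and destroy the locus resolution the rate model needs. Bins therefore never
span chromosomes, which also makes held-out-chromosome evaluation
well-defined. Continuous features are length-weighted means over the bin's
bases; uncovered bases take the chromosome mean (track-wide mean as a final
fallback), configurable off. Ambiguous (N) bases contribute nothing to
availability; soft-masked bases count by default (flag to exclude).

**Macro effects f_k.** Histogram gradient-boosted trees with Poisson loss
(shallow: depth 3, 100 rounds, learning rate 0.1, `early_stopping` off for
determinism), refit from scratch each M-step on the process's
responsibility-weighted per-bin counts with the availability-spectrum mass
as exposure. The `linear` flavor substitutes a Poisson GLM with a
weakly-informative ridge (alpha = 1e-2; a near-zero ridge lets noise slopes
hurt held-out generalization enough to lose to a constant rate). The
`constant` flavor returns 0, reducing the model to LDA-with-availability.

**Spectra effects g_km.** A baseline log-spectrum per process plus sparse
adjustments: meso-scale features enter as per-type coefficients under an L1
penalty; strand-oriented features enter through a signed covariate
(feature value × type-orientation sign) with two tiers — one
uniform-across-types coefficient (light penalty) and per-type deviations
(heavy L1) — favoring uniform strand asymmetries over type-specific ones.
The exact penalty parameterization is this package's design choice.

## Ingestion

Mutation weight = VAF/purity, the diploid (CN_tot = 2) reduction of the
copy-number multiplicity CN_mut/CN_tot; capped at 2.0 by default to guard
against VAF/purity artifacts. Missing purity defaults to 1.0 with a
warning; missing VAF falls back to weight 1.0.

Clustered mutations: for mutation *i*, the local expected rate is
μ̂_i = M_n·μ_i + M/50000 per base, where μ_i is the cohort per-base
mutation density in a 50-kb window centered on the site (windows with no
cohort coverage fall back to the genome-wide mean) and the pseudocount
M = 1 is interpreted as one pseudo-mutation added to the window — a literal
per-base +1 would make the critical distance sub-basepair and abolish
clustering. Under the null the nearest-neighbor distance is
Exp(μ̂/2) (copy-number-2 convention), so the α-quantile is
d\* = −2 ln(1−α)/μ̂ with α = 0.005 by default. Consecutive same-chromosome
mutations within min(10 kb, d\*) join one cluster, and member weights are
divided by cluster size so a cluster contributes one observation-equivalent
of mass (optionally disabled, e.g. when refitting exposures). The
calibration statistic we report is the fraction of nearest-neighbor gap
tests that reject the null, which equals α exactly under the null by
construction.

## Inference

Mean-field variational family q(π, z) = Π_n Dir(π_n | β_n) ·
Π_cells Cat(z | φ), exactly the LDA family; Y enters everywhere as
fractional counts (weights are non-integer by construction). The E-step
iterates the closed-form φ/β updates (digamma identity for E[log π]) to a
fixed point (tol 1e-8, ≤30 inner iterations), so a repeated E-step is a
no-op. φ is stored only for nonzero cells.

The M-step exploits the multinomial↔Poisson equivalence: each process's
responsibility counts are fit by Poisson regressions (trees for f_k,
closed-form baseline plus coordinate-wise proximal Newton sweeps for the
L1 g_k terms; 3 sweeps by default), and the free intercept is absorbed by
the topography normalization. The baseline refit adds 1e-2 pseudo-mutations
per type so unobserved types keep finite log-probabilities. α is updated by
Minka's fixed point on E[log π] with a floor of 1e-3. Each process update
— and the α update — is *guarded*: reverted if its ELBO term would
decrease. Full-batch coordinate ascent is therefore monotone by
construction; tree regressions alone cannot guarantee that. L1 penalties
are treated as MAP terms in the M-step objective and excluded from the
reported ELBO.

Stochastic variant: each epoch subsamples a fraction of bins for the
M-step regressions (statistics on a uniform subsample are unbiased up to a
shared scale that cancels within each regression); batch fraction 1.0
reduces exactly to full coordinate ascent. Convergence: relative ELBO
change < 1e-6 over a 10-epoch window, max 500 epochs (all configurable).
Initialization: baseline spectra from supplied reference spectra (log) or
from a gamma-perturbed empirical spectrum; f_k starts constant; one seed
drives all randomness.

## Evaluation

Multinomial pseudo-R²: S = Σ Y log p̂(b,m|n) per-sample; normalized between
the availability-proportional null p̂⁽⁰⁾ ∝ t_bm (score 0) and the
per-sample empirical saturated model p̂⁽¹⁾ ∝ Y (score 1); cells with Y = 0
contribute nothing. Held-out evaluation uses whole chromosomes: exposures
come from the fit on the remaining chromosomes, and per-sample mixtures are
renormalized over held-out bins. The Poisson pseudo-R² for comparing rate
profiles is deviance-based with the prediction rescaled to the observed
mass and a uniform null at that mass.

Ablations share folds and seeds: `full` (trees), `linear`, `lda`
(f_k = 0, baseline spectra only) and `locus_only` (K = 1). NNLS validation
pools mutations over bin groups (equal-base-pair feature octiles) and
decomposes each group's spectrum over the model's 192-type marginal
spectra with nonnegative least squares, compared to the model's own group
contribution p(z=k|G) ∝ Σ_{b∈G} p(b|k) Σ_n p(n) π_nk.

## Simulator and fixtures

The cohort simulator draws exposures uniformly from a reference pool
(preserving exposure covariance), counts ~ Poisson(γ·M_n), cells from the
process topographies, and genomic positions uniformly among the bin's
context-compatible sites; VAFs are Beta-distributed with mean purity/2
(concentration 30) and purities uniform on (0.5, 0.95), so ingestion is
exercised end to end. Simulated data therefore contain no copy-number
variation, no clustered-mutation bursts, no calling artifacts and no
feature-measurement noise; passing recovery tests demonstrates estimator
correctness under the model, not robustness to real-data misspecification.

The toy world is a ~1.2-Mb three-chromosome genome (smoothly varying GC)
with gene bodies (+strand), and replication-timing / heterochromatin /
expression tracks. The reference model's planted macro maps combine a broad
monotone trend with strong non-monotone structure (bands, an XOR, an
interaction) so that tree, linear and constant rate models are genuinely
separable; spectra concentrate 75% of mass on distinct substitution
classes. Reference burdens are lognormal with mean 125 mutations/sample
(200-sample pool), so a 100-sample cohort at γ = 4 carries ≈50k mutations —
the regime where spectrum recovery saturates at desk scale.

Benchmark problem sizes used by the test suite: recovery at
γ ∈ {1/4, 1, 4} × 100 samples with K = 4; ablations on 10 replicates of 40
samples at γ = 3; refitting on 6 samples of 12k mutations subsampled at
{100, 1k, 10k}; cluster calibration on 100k exponential-null gaps.

## Numerical choices and edge cases

* log-sum-exp normalization throughout; −inf logits only from t = 0.
* Processes with zero attributed mass are frozen with a warning rather
  than refit.
* Empty samples refit to the prior-mean exposure, flagged.
* A degenerate held-out tensor (saturated = null score) raises rather than
  returning 0/0.
* Component matching in benchmarks is Hungarian assignment on spectra
  cosine.
* Shapley attributions of f_k use an interventional value function with
  the bin feature matrix as background (64 subsampled rows): exact subset
  enumeration up to 10 features (local accuracy to machine precision),
  seeded permutation sampling beyond. Impact = 0.97 quantile of
  |attribution|; directionality = Pearson correlation (0 on zero
  variance).
* Topotype clustering: symmetrized 10-NN cosine graph, Leiden
  (RBConfiguration, resolution 0.2, seeded), UMAP (10 neighbors,
  min_dist 0.1, negative sampling rate 3, seeded). Cross-library UMAP
  parameter equivalence is not asserted.

## Known limitations

* Total copy number is not consumed beyond the diploid weight reduction;
  no indels or structural variants.
* The strand-adjustment penalty structure is a stated approximation; no
  claim of equivalence to any particular published parameterization.
* Whether the 50-kb background window is centered or tiled is a
  convention; centered is implemented.
* bigWig tracks must be converted externally; no liftover.
* Model archives are Python pickles (they embed sklearn tree ensembles);
  load only trusted files.
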