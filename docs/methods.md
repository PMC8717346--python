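# Methods notes

This note records the models, conventions and numerical choices behind
`songspace`, including the places where the design was genuinely open and
what the synthetic-data tests do and do not establish.

## Data model and input conventions

The atomic record is a song *element* (one continuous spectrogram trace)
with identifiers (song, individual, population, species, sex), start/end
times in seconds, and ~23 named acoustic measurements (duration and
frequency percentiles, bandwidths, peak-frequency-contour statistics,
spectral entropies/flatness, modulation index; frequencies in Hz). Sex
labels are lowercased and whitespace-trimmed; anything but male/female is
an error rather than a third class. Blank cells are an error for every
feature except the dominant-frequency slope, which is zero-filled: elements
too short to support a slope estimate show no meaningful modulation, so
zero is the faithful value. Song-level aggregation takes song duration as
the time span of the song's elements, element rate as count/duration, and
the song's 5%/95% frequencies as the min/max of the element-level 5%/95%
frequencies. The latter is a choice: only the *range* ("top minus bottom
frequency among all elements") is pinned down by its definition, and the
min/max reading is the one that makes the range identity hold exactly. The
element-level feature set carries `freq_95` alongside the 22-parameter
analysis set precisely so this aggregation is computable.

Correlation pruning (default |r| ≥ 0.95) scans column pairs in input order
and drops the later member, after discarding zero-variance columns; this is
deterministic for a fixed column order and idempotent. Life-history
collinearity (|r| > 0.7, pairwise-complete) is *reported*, not auto-dropped
— exclusion is an analyst decision.

## Random-forest acoustic spaces

Forests use Gini splits, minimal node size 1, and mtry of 3 (song-level) or
5 (element-level). The full-scale tree count is 10,000; the package default
is 2,000 and most tests run 150–500, with tolerance-based assertions
absorbing the Monte-Carlo differences — out-of-bag error estimates are
stable to within ±0.03 across seeds at a few thousand trees.

The unsupervised forest needs a contrast class; we use Breiman's synthetic
second class, sampling each feature independently from its empirical
marginal with the same n. Proximity between two real samples is terminal-
node co-occupancy counted over trees for which *both* samples are
out-of-bag (denominator = number of such trees); pairs never jointly
out-of-bag get proximity 0 with a warning. Both conventions (contrast
scheme, proximity denominator) are implementation decisions — alternatives
exist and are isolated behind the estimator's options. No attempt is made
to match any particular forest implementation tree-for-tree; equivalence is
statistical.

Classical MDS double-centers −D²/2 and returns eigenvector axes scaled by
the square roots of the k largest positive eigenvalues; negative
eigenvalues are reported but never embedded, and for large matrices
(n > 600) only the leading eigenpairs are extracted by Lanczos iteration
with a fixed start vector (deterministic, and equal to the dense result to
numerical precision). Non-metric MDS minimizes Kruskal's stress-1 by
alternating isotonic regression with Guttman-transform updates, starting
from the classical solution plus jittered restarts (default 4), with weak
("primary") tie handling — tied dissimilarities impose no mutual order
constraint — tolerance 1e-6 on the stress change, and a 500-iteration cap.

## MCP geometry and dimorphism metrics

The 95% MCP retains the ceil(0.95·n) points nearest the arithmetic
centroid (ties at the cut broken by input order — the retained-count
convention is ours, since round-vs-ceil is not universal among
implementations) and hulls them; degenerate hulls score area 0 and are
flagged. Areas agree with an independent monotone-chain + shoelace oracle
to < 1e-9 over thousands of random configurations.

"Combined acoustic area", the denominator of the overlap and size-
difference metrics, is read as the area of the *union* of the two sex
polygons. This guarantees overlap ∈ [0, 1]; the alternative reading (MCP of
the pooled points) is available as an option and differs only when the
union is non-convex. Centroid distances are computed after z-scoring each
embedding axis on the population's pooled songs (both sexes), making them
comparable across populations; the z-scoring uses the n−1 SD. Balanced
subsampling draws without replacement, with a child seed per iteration
derived from the master seed by counter, so equal sex sample sizes make
every iteration bit-identical and the per-iteration spread exactly zero.
Subsampling reuses the fixed embedding rather than re-embedding per
iteration (re-embedding 100× would be computationally implausible and adds
only embedding noise).

## Elaboration PCA

PCA is fitted on the correlation matrix of the five elaboration variables,
pooled across species and sexes so male and female scores share a
coordinate system (the sexes are modeled downstream, not in the PCA).
Eigenvalues therefore sum to 5. Eigenvector sign is arbitrary; the
convention here makes the largest-magnitude loading of each component
positive. PC interpretation ("song length", "element rate", "song
variability") is left to the analyst and never asserted by code.

## Bayesian phylogenetic mixed models

Gaussian responses only (all modeled responses — song parameters, PC
scores, dimorphism metrics — are continuous). The sampler is a blocked
Gibbs scheme: (i) fixed plus all latent random effects jointly from their
multivariate-normal full conditional via one Cholesky of the mixed-model
equations (the cross-product matrices are precomputed once, so each sweep
costs one q×q factorization); (ii) each variance from its scaled-inverse-
chi-square conditional; (iii) for components that declare it, a working
scalar α ~ N(alpha.mu, alpha.V) multiplying the latent effects (non-central
parameter expansion), whose conditional is a normal regression update. The
reported component variance is α²·σ²_latent. Fixed effects carry an
effectively flat N(0, 1e8) prior; this keeps the joint conditional proper
when species fixed effects alias the phylogenetically structured species
random effect — a configuration the pipeline deliberately permits (both
terms are specified, with the parameter-expanded prior regularizing the
split; a warning notes dropped *exactly* collinear fixed columns, which
are removed greedily keeping the earliest). Chains abort with a diagnostic
if any variance exceeds 1e12.

Default priors: residual (V=1, nu=0.002); random components (V=1, nu=1,
alpha.mu=0, alpha.V=625). Chain presets: sex-difference models
1,750,000/300/15 (iterations/burn-in/thin), elaboration 300,000/300/30,
dimorphism 500,000/500/30, plus desk-scale presets `test` (20,000/2,000/10)
and `reduced` (2,500/500/2) used by the test suite and replicate studies.
pMCMC is twice the smaller posterior tail mass across zero, floored at half
a stored sample and capped at 1. Credible intervals are equal-tailed 2.5/97.5%
quantiles. Effective sample size uses Geyer's initial-positive-sequence
estimator, truncated at n; lag-1 autocorrelations ≥ 0.1 are flagged. DIC
uses the deviance *conditional* on the sampled effects (2·mean D − D at the
posterior mean of the linear predictor and residual variance); the marginal
focus is not implemented. All-subsets ranking standardizes covariates and
sets missing values to 0 (the mean) first, enumerates subsets with
interactions only when their mains are present, sorts by DIC, and — where
the top models sit within 2 DIC — prefers the fewest parameters. A guard
refuses more than 12 candidate terms unless forced.

Dimorphism models have one response value per population, so the individual
random term is dropped there; species (phylogenetic) and population
intercepts remain.

Blomberg's K uses the standard observed/expected MSE-ratio form with the
phylogenetic mean â = (1'C⁻¹1)⁻¹1'C⁻¹y; it is exactly 1 on a star tree and
invariant to affine transforms of the trait and to global branch-length
rescaling. Species-level tip values are species means of the song variable
(the tip statistic is a choice; medians are one alternative). No
randomization p-value is computed. How replicate populations collapse to
one tip is likewise a choice — species means pool all songs.

## Synthetic data generator

The generator emulates the hierarchical design the analyses assume: a
pure-birth ultrametric tree (depth normalized to 1); species feature means
Brownian with variance σ²_BM·C; independent Gaussian population, individual
and song intercepts on every feature; element-level noise; and a male shift
per feature. Designated "elaboration" features additionally receive
sex-by-covariate structure: the male shift there is base + Σ slope·z(cov),
with covariates drawn uniformly from realistic per-population ranges and
z-scored across populations. The mean male shift over the elaboration
features also drives a song-level elaboration latent (shared
population/individual/song components plus the male shift) that sets the
element count and stretches element durations and gaps multiplicatively
(log-stretch = 0.5·latent), so derived song duration rises and element rate
falls with the latent and the planted interaction is visible to the
song-level analyses at approximately its nominal standardized magnitude.
Frequency-like columns are mapped onto a positive Hz-like scale with the
element 95% frequency constructed above the 5% one, keeping song frequency
ranges non-negative.

The default preset mirrors the motivating study's shape — 9 species and 15
populations (5 + 2 + 2 + six singletons) — with 4 individuals per
population (balanced sexes), 3 songs per individual, 4–9 elements per song,
hierarchical SDs (population 0.5, individual 0.5, song 0.3, element 1.0),
σ²_BM = 1, a default male shift of 1.0 on three features, and a 10%
covariate missingness rate (latitude always complete). All randomness flows
from one master seed through counter-derived child streams, so any stage
regenerates independently.

What the generator does *not* emulate: real acoustic feature correlation
structure (features are conditionally independent given the hierarchy),
measurement error correlated within recordings, species differences in
repertoire composition, or any actual fairy-wren acoustics. Passing tests
therefore establish that the estimators recover the statistical structure
they model — not that any particular field dataset would yield particular
values.

## Problem sizes and calibration protocols

Replicate studies in the test suite and acceptance script run at desk
scale, chosen so the whole suite completes in well under half an hour on
one CPU: forests of 150–2,000 trees; `reduced` chains for replicate fits;
sampler calibration at n = 600 songs / 100 individuals / 15 populations
(coverage over 100 replicates, type-I over 200); end-to-end interaction
recovery at 15 populations × 6 individuals × 3 songs with a planted
standardized slope of 0.5, 20 replicate datasets (the null band is assessed
over 15 datasets × 4 covariates × 3 PCs). These sizes were fixed as part of
the test design; power at the planted slope requires roughly this many
songs per population.

## Known limitations

- The sampler covers Gaussian responses and scalar variance components
  only; no multivariate responses, non-Gaussian families, WAIC/LOO, or
  pedigree (non-phylogenetic) animal models.
- Proportion-valued dimorphism responses are modeled on the identity scale,
  as is conventional for these metrics; estimates near 0 or 1 can leave the
  unit interval.
- MCP areas for songs with fewer than 3 distinct element positions are 0 by
  convention, which deflates element diversity for very short songs.
- With 9 species, the phylogenetic variance is weakly identified; its
  posterior leans on the parameter-expanded prior.
- Kruskal NMDS finds local optima; restarts mitigate but do not guarantee
  the global minimum.
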