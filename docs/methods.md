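# Methods

## The mixture model

A bulk methylation profile is modelled as a convex combination of cell-type
methylomes: for probe g, the bulk beta value is

    y_g = Σ_c f_c · B_gc + ε_g,

where B_gc is the mean beta of cell type c at probe g, f is the composition
(f ≥ 0, Σ f_c = 1) and ε is measurement noise. Because beta values are
bounded fractions of methylated alleles, this linearity holds to good
approximation at the probe level. The design matrix B is restricted to a
signature of probes chosen to discriminate the cell types; including a
cancer-cell class in B is what turns relative immune composition into
absolute composition with tumour purity as the cancer coefficient.

## Signature construction

For each unordered pair of cell types a two-group linear model is fitted
per probe on the beta scale. Per-probe residual variances are moderated by
the empirical-Bayes scaled-F model: s²_g | σ²_g ~ σ²_g·χ²_{d_g}/d_g with
prior σ²_g ~ s₀²·d₀/χ²_{d₀}. The prior (d₀, s₀²) is estimated by moment
matching of log s²_g (digamma/trigamma equations, trigamma inverted by
Newton iteration); the moderated t uses the posterior variance
(d₀s₀² + d_g s²_g)/(d₀ + d_g) on d_g + d₀ degrees of freedom. When the
observed spread of log-variances is no larger than the χ² sampling spread,
d₀ = ∞ and a single pooled variance is used; when the moment estimator is
degenerate (fewer than two positive variances) the code falls back to the
classical t with a logged warning. Forcing `prior_df=0` or `inf` exposes the
classical-t and common-variance limits for verification.

Selection: |Δ median β| ≥ 0.25 and BH FDR ≤ 0.01 within the contrast, at
most 100 probes per contrast. The cap ranking — ascending moderated p, ties
by descending |Δ median β|, then lexical probe ID — and the deduplication of
probes selected by several contrasts are choices this package fixes
explicitly (the heuristic itself does not determine them); both are
deterministic. Δ median β is computed from raw group medians, deliberately
robust and on the scale the thresholds refer to, while the t statistic
tests means. The exported basis holds type-wise mean beta × 100 (percent),
columns in sorted label order.

Probes with missing values are dropped from any computation that touches
them (count logged); nothing is imputed. Inputs are assumed normalised
upstream; no array-specific processing is attempted.

## Deconvolution

Per sample: restrict to signature probes present in the sample (dropped
probes logged; fewer than n_types + 1 usable probes is an error), scale the
mixture ×100 to signature units, standardise the signature by its global
mean/sd and the mixture by its own mean/sd, then fit linear ν-SVR
(C = 1.0, tol = 1e-6) for ν ∈ {0.25, 0.5, 0.75} and keep the ν whose
intercept-free reconstruction Ŝw minimises RMSE against the standardised
mixture. Negative coefficients are clipped to zero and the remainder
normalised to sum to one. These steps (grid, kernel, model selection,
clipping, normalisation) follow the published SVR deconvolution algorithm
this package re-implements; they are inherited, not invented here. Joint
standardisation of the signature (one global mean/sd rather than per
column) preserves the relative scale of the columns; whether the original
web implementation standardised jointly or separately is not documented,
so small numeric differences from it are possible.

Quantile normalisation is never applied: a global methylation shift between
tumours is a signal the cancer column should absorb, not a technical
artefact.

The permutation p-value draws pseudo-mixtures of signature length with
replacement from the observed sample's own values, deconvolves them
identically, and compares achieved Pearson correlations:
p = (1 + #{r_null ≥ r_obs})/(n_perm + 1), which is never exactly zero. Each
cohort sample's permutation stream is seeded by a stable hash of
(seed, sample id) — not the sample's position — so cohort results are
invariant to sample order while remaining bit-for-bit reproducible.

Known behaviour: at high purity the estimate is slightly compressed toward
the interior (ridge shrinkage plus clipping of noisy near-zero
coefficients of absent cell types redistributes a little mass away from the
dominant component). On synthetic data this bias is ≈0.015 noiseless and
grows with mixture noise; it mirrors the larger deviations at very high
purity reported for SVR-based purity estimation generally.

## Benchmarking metrics

Per-cell-type correlations (across samples), per-sample correlations
(across cell types), elementwise absolute error with per-type/overall
means, and a Wilcoxon rank-sum comparison of two methods' error
distributions. Exactly constant vectors yield an explicit
`defined = False` flag instead of NaN (constancy is tested by zero range,
since floating-point std of a constant vector need not be exactly zero).
Purity residuals are method − reference per sample, with a Pearson
correlation and equal-width reference-purity bins; the sign convention is
fixed so positive residuals mean overestimation relative to the reference.

## Consensus clustering and the classifier

Consensus clustering runs PAM (k-medoids) on Manhattan distances over 100
random 80% subsamples per candidate k (k = 2…6 by default), accumulating
co-assignment frequencies among co-sampled pairs; final labels come from
PAM on 1 − consensus, and k maximises the mean within-cluster consensus
(ties prefer smaller k). PAM is the classic BUILD + SWAP algorithm,
implemented here directly (deterministic given a distance matrix, lowest
index wins ties) because no installed dependency provides k-medoids. The
80% subsample fraction is a package choice; the iteration count and metric
are fixed by the procedure being replicated. With k = 2, the cluster with
the higher mean CTL (CD8) fraction is labelled *hot*; an exact CTL tie
breaks on the higher Treg mean (logged).

The cluster classifier is an elastic-net-penalised logistic regression
(saga solver; α = L1 mixing over {0.1, 0.325, 0.55, 0.775, 1.0}, penalty
strength λ over {1e-3…1e2}); (α, λ) maximise mean Cohen's κ over three
repeats of stratified 5-fold CV, computed from hard predictions at
probability 0.5, with κ ties resolved toward stronger regularisation. The
final model refits all samples; the intercept is unpenalised, so λ → ∞
yields the majority-class predictor.

## CYT, ratios, diversity

CYT = √(GZMA·PRF1) (geometric mean, scale-equivariant). The linear model
regresses log₂(CYT) on cell-fraction predictors by OLS; zero CYT values
trigger a +1 offset before log₂ in the model only (raw CYT is reported
without offset). Passing a full composition is collinear with the
intercept; the rank check (pivoted QR) raises an error naming the
collinear columns rather than silently dropping one. CD8:Treg ratios use a
symmetric pseudocount of 1e-4 to stay defined at zero Tregs; TCR diversity
is clones/reads.

## Immunoediting

Coefficients c_neo[k], c_nonneo[k] (expected neoantigenic /
non-neoantigenic nonsilent mutations per silent mutation in base-change
context k) are pooled cohort-wide as ratios of summed counts — more stable
than per-tumour averaging when per-context counts are small, and invariant
to uniform scaling of a cohort. Per tumour, expected_neo = Σ_k s_k·c_neo[k],
percent_depleted = 100·(1 − observed/expected) (undefined and flagged when
expected = 0 with observed > 0) and edited_count = max(expected − observed, 0).
Estimating coefficients from the cohort under test centres mean depletion
at zero by construction; measuring depletion requires coefficients from an
unedited calibration cohort, which is how the simulations below use it.
The six contexts are configurable labels; defaults are the six pyrimidine
base changes. Cluster association uses a negative-binomial regression of
edited counts on cluster (optional covariates), falling back to Poisson
when the dispersion estimate collapses; non-integer counts are rounded
with a warning.

## Synthetic data

`generate_reference` plants, for each pair of cell types, a block of
probes shifted +δ/2 in one type and −δ/2 in the other (δ = 0.4 by
default), leaving all other types at the probe's baseline. Each planted
probe therefore separates its own pair by δ but any contrast sharing one
endpoint by only δ/2 (< the 0.25 selection threshold), making it
informative for exactly one pairwise comparison — the property that lets
recovery tests count true and false selections unambiguously. Baselines
are Uniform(0.1, 0.9); planted probes redraw theirs from Uniform(0.2, 0.8)
so the shift cannot be clipped at the unit interval. Reference samples add
Gaussian noise (sd 0.02, n = 4 per type) with clipping to [0, 1] (clip
events logged). Mixtures are composition-weighted true type means plus
Gaussian noise. The default panel — nine cell types including a cancer
class, 5000 probes, 100 informative probes per pair — mirrors the scale of
a real tumour deconvolution panel (seven immune lineages + fibroblast +
cancer).

What the generator does *not* emulate: probe type I/II chemistry biases,
batch effects, beta-distributed (heteroscedastic, boundary-inflated)
noise, correlated probes within CpG islands, or reference/target platform
mismatch. Passing recovery tests therefore demonstrates correctness of the
algorithms under the mixture model's own assumptions, not robustness to
450k technical artefacts — those are assumed handled by upstream
normalisation.

The editing-cohort generator draws silent counts per context from Poisson
means with a C>T-dominant spectrum and nonsilent counts at planted
c_neo/c_nonneo rates, with a uniform depletion factor on neoantigenic
counts.

## Problem sizes in the test and acceptance runs

Signature recovery runs 20 independent default-scale panels (36 contrasts
× 5000 probes each). Deconvolution accuracy checks use a 9-type panel with
12 informative probes per pair (432-probe signature, 50 mixtures) — large
enough that noise sd 0.01 recovery is comfortably inside tolerance, small
enough that the ν-SVR grid stays fast. Purity recovery uses the full
default-scale signature (3600 probes, 45 samples over the 0.1–0.9 grid)
because high-purity accuracy at mixture noise sd 0.05 benefits from the
larger probe count. Permutation calibration uses a 5-type, 100-probe
signature with 200 replicates × 100 permutations. Classifier and editing
simulations use n = 60, 500 and 1000 as stated in their tests.

## Known limitations

- No confidence intervals on fractions; uncertainty is summarised only by
  RMSE/r/permutation p per sample.
- The basis assumes reference and mixtures share a measurement scale;
  cross-platform or poorly normalised inputs will bias fractions.
- High-purity compression (above) means purity > 0.9 is mildly
  underestimated under noise.
- PAM consensus clustering at n in the thousands is O(n²) per subsample;
  it is intended for cohort-level (hundreds of samples) use.
- The immunoediting expectation inherits the silent-mutation-spectrum
  assumption: contexts with few silent mutations give unstable per-tumour
  expectations.
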