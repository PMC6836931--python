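# Methods

This note records the statistical models, the defaults and why they were
chosen, the numerical details, and what the synthetic data can and cannot
certify.

## Count model and the differential test

Counts `y_gj` for transcript `g` in sample `j` are negative binomial with
mean `q_{g,t(j)} · s_j` and per-transcript dispersion `α_g`
(`Var = μ + αμ²`). Size factors `s_j` follow the median-of-ratios rule —
the per-sample median of `y_gj / geomean_g(y_g·)` over transcripts positive
in every sample — rescaled to geometric mean 1; a pseudo-reference flag
(adds 1 before forming the reference) covers sparse matrices with no
always-positive transcript.

The full model fits one mean per time group, the reduced model one shared
mean. Given `α`, group means are the root of the score equation, solved by
a damped fixed-point iteration (vectorised across transcripts; 30
iterations, floor 1e-8). The dispersion is estimated per transcript by
maximising the Cox–Reid–adjusted profile likelihood — the standard
small-sample correction subtracting `½ log det(XᵀWX)`, `W = μ/(1+αμ)` —
with a vectorised golden-section search on `log α ∈ [log 1e-8, log 50]`
(45 iterations). Plain ML dispersion is biased low when three means are
fitted to 24 samples, which inflates the test. Non-finite estimates fall
back to method-of-moments, flagged in the result.

The LRT statistic `2(ℓ_full − ℓ_red)` uses the full-model dispersion in
both likelihoods. Its reference distribution is **F**: `LRT/df₁` against
`F(df₁, N − k)` with `df₁ = k − 1` groups and `N` samples. The asymptotic
χ² reference is anticonservative at this design size (empirical type-I
≈ 0.08 at nominal 0.05 on null simulations); the moment-matched F reference
brings it to ≈ 0.04–0.06. This is a deliberate choice of reference, not a
different statistic; the `df` column still reports `k − 1`. The test is
intentionally simplified relative to full DE frameworks: no
dispersion-trend shrinkage, no outlier refitting, no independent filtering.
All-zero transcripts are dropped before testing and reported.

The variance-stabilising transform is `log2(count/sf + 1)` — monotone,
adequate for PCA QC and correlation clustering, and documented as a
stand-in rather than a delta-method VST. PCA operates on transcript-centred
samples via full SVD.

The design power analysis evaluates one-way ANOVA power with the
noncentral F distribution (`df₁ = k − 1`, `df₂ = k(n−1)`, `λ = f²kn`) and
returns the smallest per-group `n` reaching the target, by exponential
bracketing plus bisection. At `f = 0.7, α = 0.05, power = 0.8, k = 3` it
returns 8 per group — the design size the pipeline assumes throughout.

## Co-expression modules

Signed adjacency `((1+cor)/2)^β` keeps only positively co-varying
transcripts together, which matches the module interpretation downstream
(a module's eigengene should be a coherent temporal profile, not a mix of
anti-correlated arms). β is the smallest candidate whose scale-free fit R²
(regression of `log10 p(k)` on `log10 k` over ten equal-width connectivity
bins, sign-penalised for positive slopes) reaches 0.8. Planted block
structures are *not* scale-free, so on simulated data the criterion is
typically unreachable; the pipeline then falls back to the hardest
candidate (β = 30 on the default grid), which sharpens block contrast
instead of blurring it. The TOM is
`(l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with `l_ij = Σ_{u≠i,j} a_iu a_uj`
and unit diagonal.

Module detection is average-linkage clustering of `1 − TOM` with a static
cut at height 0.99 and a minimum module size of 20; undersized clusters
fall into the unassigned class (label 0) and surviving modules are numbered
by decreasing size. This static cut approximates a dynamic hybrid tree cut
with a simpler deterministic rule; it recovers clean planted blocks exactly
but will fragment gradient-like structures more readily than the dynamic
algorithm. Eigengenes are the leading right singular vector of the
standardised module expression, unit norm, sign-fixed to correlate
positively with the module mean profile.

## Enrichment layers

Hypergeometric enrichment uses the upper tail `P(X ≥ x)` with the
population equal to the chosen universe; terms with zero overlap are not
tested; BH correction runs across tested terms; the filter keeps FDR
strictly below 10⁻⁴. For DET-level enrichment the universe is all tested
(non-zero) transcripts; for module groups the universe is the DET list
itself, so `N` is the DET count and `B` a term's DET-wide count — exactly
the frame of the module z-score.

The module z-score is a continuity-corrected binomial approximation:
`z = (x − 0.5 − B·n/N)/√(n · B/N · (1 − B/N) · c)`. The variance factor
`c` defaults to 1 (the standard binomial variance); `c = 2` is exposed as
`variance_factor`/`zscore_variance_factor` for the alternative convention
in which the variance term is doubled. Both are available; nothing in the
pipeline silently prefers one beyond the default. `B ∈ {0, N}`
makes the variance degenerate and raises.

Module combinations are enumerated as all non-empty subsets (capped at six
modules) of the modules with the most enriched terms, named `[i;j;…]`.
Best-predictor assignment credits each enriched term once, to the group
with maximal z; ties break toward the smaller group, then the
lexicographically smaller name — deterministic and biased toward the more
specific predictor. Process rollups report per-category percentages over
classified terms (summing to 100) with unclassified terms counted
separately.

## TF scoring

Gene-level hit counting replaces nucleotide-window binding-site scanning:
the package consumes precomputed TF → target gene sets (GMT) standing in
for promoter scans, because the scoring mathematics — not motif discovery —
is what the downstream network analysis depends on. Per TF the 2×2 table
(DET/background × target/not) gives a one-tailed Fisher exact p computed as
the hypergeometric upper tail, `F = −ln p`, and the binomial z uses the
background hit rate `p₀ = hits_bg/n_bg` with a 0.5 continuity correction.
The F floor is strict (`F > 20`); grouping uses |z| against strictly
decreasing cuts (35, 25, 15, 10, 2), which makes the five groups nested by
construction. A degenerate background rate (`p₀ ∈ {0,1}`) flags the record
out of grouping rather than fabricating a z. The default background is the
tested non-DET transcripts.

## Network growth and selection

Expansion is greedy and deterministic: at each step the external node with
maximal summed edge confidence into the current network joins; ties break
toward higher total degree, then the lexicographically smaller id. The
default schedule (5, 5, 10, 10, 10) reads the cumulative layer sizes
+5/+10/+20/+30/+40 as totals added; it is fully configurable because the
alternative reading (alternative first-layer sizes) is also plausible.
Growth % is relative to the seed layer. Saturation (no external neighbour
left) is flagged and freezes subsequent layers.

Layer scoring reuses the hypergeometric machinery on the network's
annotatable nodes (universe = tested transcripts; TF/hub ids without
annotations drop out). Sensitivity and specificity are shared-term
percentages of the DET-derived and network-derived term sets respectively.
Selection takes layers with sensitivity ≥ 40 and growth ≥ 150, maximises
specificity, and breaks ties toward fewer nodes then the lower TF group; if
no layer qualifies the maximal-sensitivity layer is returned flagged
`relaxed`. The k-means partition (k = 3, 50 restarts, fixed seed) uses
within-network degree, summed confidence and closeness centrality,
standardised; clusters ranked by mean degree map to core / secondary /
peripheral. The feature set is a documented choice — the procedure's
source does not specify one.

## Synthetic data: what it emulates and what it does not

The generator mirrors the study design: 3 time points × 8 animals, NB
counts with per-transcript log-normal baselines (σ = 1 around a median of
100) and dispersion 0.05 — typical bulk RNA-seq values. Three planted
modules follow the observed temporal archetypes: an 80-transcript transient
45-min induction, a 100-transcript 24-h increase, a 70-transcript 24-h
decrease, each at |log2 effect| = 2 (4-fold — the magnitude of strongly
induced acute-response transcripts such as early chemokines) with a
within-module latent factor of weight 0.4
(`μ ∝ exp(w·f_s − w²/2)`, `f_s ~ N(0,1)` shared per module and sample),
giving within-module correlations around 0.7 while preserving marginal
means. Surgeon and batch columns are generated with zero effect by default
(a configurable batch effect exists for PCA QC exercises), matching a
design in which neither clustered the samples.

Annotations plant two terms of 20 genes per module (≥ 70% drawn from the
module; a noise fraction, default 10%, from the background) among 60 terms
total, each carrying one process category (the transient module's terms are
"upstream signalization"). Five of fifteen TFs are driven — 80% of their
60 targets drawn from the planted differential transcripts. The PPI graph
wires a hub to every driven TF through two mediators (confidences
0.95/0.9), attaches each driven TF to ~15 annotated differential genes
(0.6–0.8), and adds ~3 random low-confidence edges per background node.
Driven TFs connect preferentially to *annotated* genes so that grown
networks carry a recoverable GO signature — emulating the dense annotation
of curated interaction databases.

What passing tests therefore certify: the machinery recovers structure it
was designed to detect, at realistic design sizes and noise. What they do
not certify: robustness to unmodelled features of real data — GO DAG
redundancy, annotation bias, dispersion–mean trends, outlier samples,
batch-confounded designs, UMI/single-cell structure, or PPI edge noise
correlated with study bias.

## Problem sizes and determinism

Default runs use 2000 transcripts (250 planted differential), which keeps a
full pipeline run under ~2 s and the whole validation suite around half a
minute while leaving every stage's statistics in their intended regime;
the simulator scales to larger designs if heavier runs are wanted. All
stages are deterministic given the design seed: generators use a single
`numpy` Generator per stage, greedy expansion has total tie-breaking, and
k-means uses a fixed random state. Two runs with the same config and seed
produce byte-identical manifests.

## Known limitations

- The static tree cut can split one planted module across two labels when
  within-module correlation is weak; the dynamic hybrid cut it approximates
  is more forgiving.
- The F-reference LRT is calibrated for the 3×8 design family it targets;
  designs with very few replicates per group (2–3) will again drift
  liberal because the dispersion estimate degrades.
- The module z-score's normal approximation is poor when `B` is within a
  few counts of 0 or `N`; such terms rarely survive the FDR filter, but the
  z value itself should not be over-read there.
- Specificity of tiny networks is noisy: one or two enriched terms swing it
  between 0 and 100; the selection rule's sensitivity and growth floors are
  what keep this from mattering.
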