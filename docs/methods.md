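# Methods

This note documents the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic data
generator does and does not emulate, and the numerical conventions that
make runs reproducible.

## Count model and synthetic data

Spectral counts are modeled as negative binomial with a quadratic
mean–variance law, Var(X) = μ + φμ², with a single overdispersion φ shared
across proteins and protein baseline means drawn log-normally
(meanlog 2.3, sdlog 1.2 → median ≈ 10 spectra, right-skewed, matching the
dynamic range typical of a few-thousand-protein label-free run).
Differential proteins receive a multiplicative shift of 2^±effect_log2 in
every non-reference group, direction uniform. Detection dropout is modeled
as independent thinning: each cell is zeroed with probability
1 − detection_prob, on top of the abundance-dependent zeros the NB itself
produces.

Defaults (the simulated study conditions): 4,000 proteins, two groups of
8 samples, de_fraction 0.1, effect_log2 1.5 (≈ 2.8-fold, the size of
change the downstream |fc| ≥ 3 filter targets), φ = 0.5, detection_prob
0.95, 500 gene sets of size 10–50 with 10% planted (80% of a planted
set's members drawn from the differential proteins). detection_prob is
deliberately mild: uniform thinning is abundance-independent, so each
dropped high-abundance cell is a large outlier on the normalized scale;
rates much above ~10% would swamp realistic effect sizes, which real
(abundance-dependent) missingness does not do. This is the main respect
in which the generator is less forgiving than real data at equal rates —
and conversely the generator has no batch structure, no correlated
proteins (outside planted sets), and no shared-peptide ambiguity, so
passing tests demonstrate correctness of the machinery and calibration
under the stated model, not performance on any particular instrument's
output.

Peptide evidence is generated by Dirichlet-multinomial splitting of each
protein's counts over 1–5 synthetic peptides; summing peptides exactly
recovers the protein matrix, which is the invariant the protein-inference
stage is tested against.

A second generator (`simulate_normal_groups`) emits Gaussian matrices on
the normalized scale with unit within-group SD, so a planted effect is
exactly the stated number of pooled SDs. The differential-stage
calibration and power benchmarks use it; the count → normalization path
is exercised by the end-to-end pipeline benchmark instead.

## Protein inference and filtering

A protein is kept iff ≥ 2 distinct peptides were observed for it (across
all samples); its count is the sum of its peptides' counts. The detection
("variation") filter keeps proteins with nonzero counts in ≥ 4 samples,
counted across the whole matrix rather than per group — the literal
reading of the rule, and the conservative one for a 16-sample design.
Both thresholds are configurable.

## Variance stabilization

Each sample j is first calibrated by a scale s_j = median(x_ij / ref_i)
over cells nonzero in both the sample and the geometric-mean
pseudo-reference ref_i = exp(mean_j log(1 + x_ij)) − 1. The calibrated
values y = x/s_j are then transformed with

    g(y) = (2/√φ̂) · asinh(√(φ̂ · y)),

where φ̂ is the median moment estimate of (v − m)/m² across proteins.
g is the exact variance-stabilizing transform for Var = μ + φμ²: Var(g) ≈
1 independently of the mean, which is verified in the tests by regressing
row SD on row mean after transform (slope within ±0.05 on NB data at
φ = 0.5). g is monotone within each sample, maps 0 to 0, and the
calibration removes exact between-sample scalings identically. Offsets
are fixed at zero — spectral counts have a true zero, so only a scale is
calibrated. Zeros are kept, never imputed. An all-zero sample cannot be
calibrated and is an error.

## Differential abundance (ROTS)

Statistic family: d = |m̄₂ − m̄₁| / (α₁ + α₂·s), s the pooled-variance
standard error. (0, 1) is the absolute t statistic; (1, 0) the absolute
mean difference. Candidates are (α₁, 1) for α₁ ∈ {0, 0.01, 0.05, 0.1,
0.5, 1, 2, 5} plus (1, 0).

Optimization: B bootstrap pairs are drawn by resampling samples with
replacement within each group; for each candidate statistic and each
top-list size k ∈ {25, 50, 100, 200, 400} the mean top-k overlap R_k is
compared to the same quantity R⁰_k on group-label-permuted data (one
permutation per bootstrap pair, resampled under the permuted labels), and
Z_k = (R_k − R⁰_k)/sd_k is maximized; sd_k is the bootstrap SD of the
observed overlaps, floored at 1e-12 to keep the k = n row (overlap
identically 1) finite. Ties break toward smaller α₁, then smaller k; the
(1, 0) candidate is considered last. All candidates see the same
pre-drawn resampling plans, so the comparison is paired.

Inference: P group-label permutations, pooled null across proteins —
p(g) = (1 + #{null d ≥ d(g)}) / (1 + n·P) — with add-one smoothing so
p > 0 always. Pooling assumes the per-protein null distributions are
exchangeable, which the variance stabilization is there to deliver; the
calibration benchmark (2,000 null proteins, 8 vs 8) checks the realized
type-I error at 0.05 stays within [0.035, 0.065]. The permutation FDR at
d(g) is (mean per-permutation null exceedances)/(observed exceedances),
clipped to [0, 1] and made monotone non-decreasing from the top of the
ranking by a reverse running minimum. Defaults B = 500, P = 1000; the
benchmarks use B = 100, P = 500, which leave both operating
characteristics unchanged within Monte-Carlo error. Selection: p < 0.05
(strict) and FDR ≤ 0.25 (inclusive).

## Absolute GSEA

The ranking metric is |d|, descending; ties are broken by a seeded
shuffle recorded in the run manifest, so no accidental lexicographic
structure enters the set statistics. The running sum increments
|r_i|^p / Σ_hits |r_j|^p at hits (p = 1 by default) and decrements
1/(N − N_H) at misses; ES is the value at the maximal absolute deviation.
If every hit metric is zero the hit weights degenerate and equal weights
are substituted. With p = 0 the statistic reduces to the classical KS
running sum (tested against a direct computation; when the positive and
negative excursions tie exactly in magnitude the reported sign is the
first-attained extreme).

The null permutes gene labels — random same-size subsets of the universe
— rather than sample labels: with 8 + 8 samples, sample permutations are
plentiful, but the pipeline keeps gene-label permutation as the default
so that behavior is unchanged for smaller designs where sample
permutation is hopeless. NES = ES / mean(|null ES| of matching sign);
nominal p = (1 + #{|null ES| ≥ |ES|}) / (1 + P), two-sided on magnitude.
Significance is nominal p < 0.05 with no cross-set FDR, matching the
selection convention of the prioritization stage. Sets overlapping the
universe by < 3 members are skipped. The batched collection runner draws
one null sample per distinct set size (null ES depends on the set only
through its size) from deterministic child seeds; the single-set entry
point draws fresh nulls, which the calibration benchmark relies on.

The enriched component of a significant set is its leading edge: members
at ranks ≤ peak for positive ES, ≥ peak for negative ES. ("All members
present in the data" would be the alternative reading; the leading edge
is the subset that actually drives the score, hence the default.)

## Prioritization cascade

Frequency(protein) = number of significant pathways (pooled over
collections and contrasts) whose leading edge contains it. The percentile
cut uses the nearest-rank definition — threshold = the ⌈q/100·n⌉-th
smallest frequency — with all ties at the threshold included:
deterministic and conservative. Fold change is computed on the count
scale with pseudocount 1 on both group means, r = (m_test + 1)/(m_ref + 1),
reported as r if r ≥ 1 else −1/r so the ±3 thresholds are symmetric; both
the fold-change (|fc| ≥ 3) and spectral-count (total ≥ 10) thresholds are
inclusive. The three filters are computed as independent flags and
conjoined, so they commute by construction.

Over-representation of the candidate set in each disease-library term is
the one-sided Fisher exact (hypergeometric tail) p, with the universe
being the quantified-and-filtered proteins, not the genome — anything not
detectable in the experiment cannot count toward either margin. Terms at
p < 0.05 are significant, and each candidate's disease frequency is the
number of significant terms containing it; count ≥ 1 defines the
clinically related subset.

## Pipeline, seeds, determinism

All randomness flows from one root seed through named substreams
(`SeedSequence([root, crc32(stage), index])`), so stages are individually
re-runnable and the whole run is reproducible; floats are written with a
fixed `%.10g` format, making repeated runs byte-identical (the manifest,
which carries timestamps, is the one exception and is written last as the
completion marker). Figure products are exported as data only: PCA scores
with explained-variance fractions, Ward/Euclidean linkage leaf orders,
volcano source tables, reproducibility curves (mean ± SD of bootstrap
top-k overlaps, observed vs null).

The default end-to-end run (4,000 × 16, 500 sets, B = 500, P = 1000)
takes ~20 s on one CPU. Benchmarks in the test suite use 2,000-protein
designs with B = 100, P = 500 and the full default pipeline run twice;
the whole suite completes in about a minute.

## Known limitations

- Exact agreement with any specific VSN implementation is not claimed;
  the transform shares its contract (calibrate, then glog; flat SD–mean
  trend) but uses moment estimation rather than a full ML fit.
- The pooled permutation null assumes post-normalization exchangeability
  across proteins; strong residual heteroscedasticity would distort the
  pooled p-values (the α₁ > 0 statistics damp, but do not remove, this).
- Frequencies are pooled across collections and contrasts before the
  percentile cut; a per-collection percentile is a defensible alternative
  the API exposes but the pipeline does not default to.
- Disease annotation in simulation mode uses synthetic libraries; with
  real GMT libraries the same code path applies, but term-size bias and
  annotation redundancy in real libraries are not modeled.
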