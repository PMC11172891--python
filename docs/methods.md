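# Methods

This note documents the statistical procedures tearomics implements, the
choices made where the design was open, and what the synthetic-data tests
do and do not establish about real data.

## Differential-expression pipeline

### Filtering

Protein groups pass four sequential identification filters: (1) at least 2
identified peptides; (2) not flagged as a contaminant (the flag is taken
from the upstream search-engine annotation, not recomputed from sequence);
(3) at least 8 non-missing quantifications in the patient group *and* in
the control group; (4) at least 9 non-missing quantifications among female
samples and 8 among male samples (strata pooled across disease groups).
The counts per rule are reported in the run log. Filtering is idempotent;
thresholds exceeding the size of a stratum raise an error naming it.

### Variance-stabilizing normalization

Raw label-free intensities are calibrated per sample by a generalized-log
transform, h_s(x) = arsinh(a_s + b_s·x)/ln 2 with b_s > 0, reported in
log2-equivalent units. Parameters are fit by alternating (i) a reference
profile (per-protein median of transformed values over complete cases) and
(ii) per-sample trimmed least squares against that reference (trim
fraction 0.1), to a relative parameter tolerance of 1e-6 or 50 iterations;
non-convergence warns and keeps the best iterate. This is a least-squares
calibration, not a full robust maximum-likelihood fit: its contract is
rank preservation within samples, exact collapse of affine-transformed
replicates, and reduction of the intensity-dependence of residual spread
relative to a plain log2 transform — all covered by tests. On noisy data
the parameters can keep wobbling below meaningful levels without formally
reaching the tolerance; the warning is informational in that regime.
Log2-scale input tables skip normalization.

### Imputation

Missingness in label-free proteomics is predominantly left-censored: the
probability of a missing value rises as true abundance falls below the
detection limit. Missing cells are imputed per sample by draws from
Normal(μ_s − 2.5·σ_s, (0.3·σ_s)²), where μ_s and σ_s are the mean and SD
of the sample's *observed* protein intensities ("sample standard
deviation" resolved to per-sample statistics on the protein-group matrix).
Observed cells are never modified. Both factors are configurable
(`downshift_factor`, `width_factor`).

### Moderated t test

Per protein: log2FC = mean(patients) − mean(controls), residual variance
s² on d = n₁+n₂−2 df. The prior (d₀, s₀²) is estimated by matching moments
of e = ln s² − ψ(d/2) + ln(d/2): ψ′(d₀/2) = var(e) − ψ′(d/2) solved by
Newton on the trigamma (d₀ = ∞ when the right side is non-positive, in
which case all variances collapse to s₀² and the reference distribution is
normal), and s₀² = exp(mean(e) + ψ(d₀/2) − ln(d₀/2)). The posterior
variance is s̃² = (d₀s₀² + d·s²)/(d₀+d) and t = log2FC/(s̃·√(1/n₁+1/n₂)) on
d₀+d df. This is numerically identical to the standard empirical-Bayes
treatment in limma's eBayes, which a test verifies to ~1e-8 via Rscript.
Setting d₀ = 0 recovers the ordinary pooled-variance t. p-values are
BH-adjusted across proteins within each imputation cycle.

### Significance curve and stability

A protein is significant when p_adj ≤ τ(|log2FC|) with

τ(l) = 0 for l ≤ 1, else p_max·exp(−c/(l−1)), p_max = 0.05,
c = curve_factor·σ̂, curve_factor = 0.1.

The published description fixes only the curve's asymptotics (maximum 0.05
at large fold changes, decaying to 0 at |log2FC| = 1, rate 0.1 × an
"overall standard deviation"); the exponential form here satisfies those
constraints — continuous, strictly increasing, supremum p_max — and is
recorded in the run log so an alternative form could be substituted. The
"overall standard deviation" is read as the SD of the log2 fold-change
vector (`sd_reference="lfc_sd"`); the alternative reading (SD of all
intensities) is available as an option. The curve implies every hit has
|log2FC| > 1, i.e. fold change ≥ 2 or ≤ −2.

The impute→test→BH→curve cycle runs 20 times with independent sub-seeds;
the headline `significant` column is cycle 1 (no cycle is privileged in
the published description; the first is the reproducible choice), and
`stable` flags proteins significant in every cycle. BH and the curve are
recomputed per cycle — applying them once on pooled cycles would make the
stability flag vacuous.

## Microbiome statistics

Tables are taxa × samples relative abundances with rank-prefixed lineage
strings (`k__…|p__…|s__…`). Aggregation sums within a rank and conserves
per-sample totals to 1e-9. Rare-taxon lumping removes taxa whose mean
abundance is below 1% within *each* comparison group and pools their mass
into an "Under 1%" row (a per-sample-mean variant is available by flag);
the group-wise rule is chosen because lumped fractions are reported per
group in this kind of study. Shannon diversity uses the natural log (the
ecology default; the base is a convention, not a result). Community
comparison performs PCA on feature-scaled (z-scored) abundances and
PERMANOVA on Euclidean distances of the same scaled matrix, matching the
scaled-PCA workflow; Bray–Curtis on raw abundances is offered as an
option. Permutation p-values use the add-one formula, so the smallest
attainable p is 1/(n_perm+1) with the default 1000 permutations. The
presence/absence association builds a 2×2 table at a detection threshold
of zero (any nonzero abundance counts as positive) and applies the
two-sided Fisher test by hypergeometric enumeration with the
probability-mass rule (tables at most 1+1e-7 times as probable as the
observed one are summed).

Two 2×2 variants of the sex-balance check are provided — Pearson
chi-squared with and without Yates continuity correction — because
published demographic tables of this design do not always state the
variant; both are exposed and tested against hand-evaluated statistics.

## Synthetic data

The proteome generator draws log2 intensities
x[g,s] = baseline_g + effect_g·1(patient) + ε, ε ~ N(0, σ²_g), with
σ²_g ~ scaled-inv-χ²(d₀_true, s₀²_true) so the empirical-Bayes estimator
can be validated by parameter recovery. Missingness follows a logistic
left-censoring curve P(missing | x) = 1/(1+exp(slope·(x − midpoint))) —
the mechanism the downshift imputation presumes; real acquisition does not
specify one, so a smooth monotone curve with a configurable midpoint and
slope is the minimal model.

Default study conditions (chosen once as the generator's definition of the
cohort): 2250 protein groups; 16 patients (7F/9M) vs 16 controls (10F/6M);
10% truly differential with effect sizes N(0, 1.5²) log2 units; baseline
means N(25, 2.5²) log2 (typical LFQ dynamic range); within-protein
variance prior d₀ = 4, s₀² = 0.09 (within-group SD ≈ 0.3 log2, typical of
well-quantified label-free data); censoring midpoint 23 and slope 0.8
log2⁻¹, giving ≈ 25–30% missing values concentrated in low-abundance
proteins; 5% of proteins carry a single peptide so the peptide filter is
exercised; ages N(76.5, 7.5²) and N(68.1, 7.5²) years.

The microbiome generator draws per-sample Dirichlet compositions over 40
species in 4 phyla with a geometric-decay concentration vector (ratio 0.8,
total mass 30), so a few species dominate as in real conjunctival
profiles; the marker species has its own concentration share (mass 0.6,
mean ≈ 2% when present) and is zeroed-and-renormalized in samples where a
group-specific Bernoulli (default prevalences 0 in patients, 7/16 in
controls) makes it absent. Compositions sum to 1 exactly.

All stochastic steps derive sub-streams from one integer seed via
`numpy.random.SeedSequence` spawn keys (`child_rng(seed, *keys)`), so runs
are bit-reproducible and any cycle can be re-run in isolation.

**What the synthetic data does not emulate:** peptide-level structure and
protein inference, correlated proteins (co-regulation), batch/run-order
effects, match-between-runs artifacts, compositional sequencing noise
(read counts), contamination, or age/sex confounding of expression.
Passing recovery tests therefore demonstrates the statistical machinery is
correct under its stated model, not that the pipeline is robust to every
failure mode of real MS or metagenomic data.

## Numerical choices and problem sizes

- Fisher enumeration tie tolerance: relative 1e-7 on the hypergeometric
  mass; degenerate margins return p = 1.
- Welch with both variances zero: p = 1 for equal means, p = 0 (with a
  warning) otherwise.
- PCA drops zero-variance features before scaling and fixes signs so each
  component's largest-magnitude loading is positive.
- PERMANOVA permutes group labels; permutation F-statistics are computed
  by einsum over group indicator matrices (exact, no approximation).
- The trigamma inverse uses Newton iteration from 0.5 + 1/y.
- Validation studies run at deliberately modest sizes — e.g. 2000-protein
  null cohorts over 5 seeds, 200-replicate calibration studies with
  200–1000 permutations, a 5000-protein prior-recovery study — sizes at
  which the binomial/Monte-Carlo error bands quoted in the tests are
  already decisive.

## Known limitations

- The vsn-style calibration is least-squares, not the original robust-ML
  formulation; it matches on clean data but is not numerically identical
  on heavy-tailed data.
- Only the two-group design is supported (no covariates; age adjustment
  and mixed-model association analyses are out of scope).
- One-way PERMANOVA only; no strata or multi-factor designs.
- The significance curve applies a literal threshold function to adjusted
  p-values; fudge-statistic (SAM-like) formulations are not implemented.
- Printed demographic chi-squared values from studies of this design are
  not always reproducible from the printed counts (neither Pearson nor
  Yates); both variants are provided without privileging either.
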