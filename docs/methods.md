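# Methods

This note records the models behind each stage, the parameters that matter
(with defaults and why), the numerical decisions, and what the synthetic
data do and do not establish about real data.

## Count model and simulation

Counts are negative binomial with variance μ + αμ² (α = dispersion), the
standard overdispersed model for biological replicates of bulk RNA-seq.
Defaults model a desk-scale two-group colon experiment:

| parameter | default | rationale |
|---|---|---|
| `n_per_group` | 5 | animals are housed five to a cage; one cage per condition |
| `n_genes` | 1000 | expressed-gene scale that keeps every run in seconds |
| `n_perturbed` | 100 (half up, half down) | ~10% perturbed, the order observed in colitis colon tissue |
| `lfc_magnitude` | 1.5 (log2) | a clearly biological but not dramatic shift |
| `dispersion` α | 0.2 | typical for inbred-mouse tissue replicates |
| `baseline_log_mean`, `baseline_log_sd` | 5.5, 1.0 (natural log) | mean ≈ 245 reads; spread covers two decades of expression among *filtered* (expressed) genes — the simulator emulates the post-filter gene set, not the whole annotation |
| `library_size_cv` | 0.3 | realistic depth variation; makes normalization non-trivial |

Perturbation multiplies the treated group's mean by 2^±lfc, so the planted
group-mean ratio is exactly 2^lfc in expectation. Library depths are
log-normal with mean 1.

What passing tests show: the pipeline recovers planted effects at the
stated rates *under this generative model*. What they do not show: behavior
under gene-gene correlation, outlier samples, batch effects, or
heavy-tailed dispersion heterogeneity — none of which the generator
produces.

## Normalization

Two-stage global scaling. Stage 1 multiplies each sample by
median(library sizes)/library size; stage 2 by target/uq_s where uq_s is
the sample's 75th percentile (linear-interpolation quantile — dialects
differ, so this is pinned) of stage-1 counts over its present genes, and
the target is the cross-sample median of those percentiles. The quartile
stage runs last so the quartile constraint holds exactly in the output;
`norm.mode` restricts to either single stage. The presence threshold is
inclusive at 10 reads (10 is the smallest reliable count). Whether the
quartile should be taken over all genes, nonzero genes or present genes is
a genuinely open choice; it is exposed as `quantile_genes` with default
`present`.

Invariance: the normalized matrix is unchanged under depth rescaling of a
sample provided the presence mask and the median library size are
unchanged; for power-of-two scale factors the agreement is bit-exact
(binary floating point commutes with /2). The acceptance check exercises
exactly that regime (counts bounded away from the presence threshold,
deepest sample scaled up); outside it the invariance holds up to the shift
in the anchor statistics.

## Differential expression

Genes must be present in every sample of their higher-expressing group
(ties resolved toward group A). Fold change is the ratio of arithmetic
mean normalized expression, stored as magnitude ≥ 1 plus direction. The
selection is FC ≥ 1.5 *and* p ≤ 0.01, both inclusive, with no multiplicity
control — deliberately mirroring the upstream analysis this package
re-implements. (The source text's "p-values of at least 0.01" is read as
p ≤ 0.01: a significance selection cannot require large p-values. The
direction is configurable.)

**Test.** Exact conditional NB test: with both groups on a common scale
after normalization, group sums are rounded to integers, the total K is
conditioned on, and the two-sided p sums P(K_A = k | K) over all splits
whose probability does not exceed the observed split's (a 1 + 1e-12
relative tolerance absorbs float ties, so the modal split yields p = 1).
For NB with fixed dispersion the conditional law is free of the unknown
mean, so the test is exact up to discreteness and dispersion estimation.
Supports up to 10,000 outcomes are enumerated fully; beyond that the
support is *windowed* to ±12 conditional SDs around the conditional mean
(widened to include the observed split). The window keeps the computation
exact to well below float precision at bounded cost; a normal
approximation was measured to be ~2x anti-conservative at p ≤ 0.01 for
high-expression genes and is not used.

**Dispersion.** Per gene, the pooled within-group residual variance s² and
overall mean μ̂ give the moment ratio (s² − μ̂)/(μ̂² − s²/n); the
denominator subtracts the upward bias of μ̂² (E[μ̂²] = μ² + σ²/n), guarded
so a noisy s² cannot collapse it. The default `pooled_mom` averages these
ratios over genes with mean ≥ 20, where each ratio has bounded variance
(≈ 2α²/df), giving a stable estimate even at n = 5 per group; `per_gene_mom`
keeps the raw per-gene values but is markedly anti-conservative at this
sample size. Negative estimates are clamped to 1e-8 and logged.

Measured operating characteristics under the default conditions (10
replicates total, α = 0.2): null rejection ~0.008–0.011 at p ≤ 0.01;
planted-gene recall ~0.82 at |log2FC| = 1.5; false-discovery proportion
~0.10 — the FDP sits at the edge of 0.1 by construction: with ~890 tested
null genes, even exactly nominal calibration yields ~9 false positives
against ~82 true positives, and there is no multiple-testing correction to
push it lower.

## Metasignature

Per-list filter |FC| ≥ 1.5 and p ≤ 0.05 (both inclusive); admission
requires votes ≥ 9 of 18, mean |FC| ≥ 2 *over the voting lists* (a gene
absent from a list has no fold change there), and direction consistency.
`strict_all` (default) reads "consistently" literally — every voting
occurrence shares one sign; `majority` is provided. Whether votes are
counted pre- or post-filter is implicit upstream; post-filter is used.
Output is sorted by votes, then mean FC, then gene id.

The bioset generator plants each signature gene into a list with
penetrance 0.7 (expected votes 12.6/18), |FC| log-normal with mean 2.5 and
log-sd 0.2 (trimmed at 1), and strongly significant p (10^-U(1.5,6));
noise genes intrude at rate 0.02 with random direction and p ~ U(0, 0.05).
Under these conditions recall of the planted signature is ~0.97 and noise
admission ~0.

## Cross-species overlap

Mouse genes map through a partial ortholog table (one-to-many resolved to
the first-listed pair by default; `keep_all` expands). The default
universe is the set of genes measurable in both species through the map —
the upstream analysis names neither its universe nor its test, so the
standard hypergeometric upper tail P(X ≥ k) is used; the acceptance check
verifies it against a permutation null. Direction concordance is counted
when both sets carry directions.

## Open field

The apparatus is a beam grid (pitch 2.54 cm, 16 × 16 by default — the
commercial frame's geometry is unpublished, so it is configuration). The
animal's relocation reference starts at the center of the field, where
animals are placed. Definitions:

- *basic movements*: every horizontal break event;
- *ambulation*: a horizontal event whose beam position differs from the
  last registered position by ≥ 1 beam index (city block; the threshold is
  configurable since "complete relocation" is not quantified);
- *fine movements*: the remaining horizontal events (vertical events are
  not counted as fine movements);
- *rears / rearing time*: vertical episodes and their summed durations;
- *immobility*: session time not covered by any break interval;
- *rest*: break-free gaps strictly longer than 15 s, counted at full
  length (the definition names the gap, not the excess), leading and
  trailing gaps included;
- *distance*: beam pitch × city-block index displacement over relocations.

Counts bin by the event's start time; durations split across bins by
actual overlap, so the twelve 5-minute bins sum to the session value for
every metric. Ratios with zero denominators (no rears, no ambulation) are
reported missing, flagged, and excluded from group statistics.

The generator draws a marked Poisson stream of rear/ambulation/fine
episodes (exponential pauses at the summed rate); arrivals during an
active episode are dropped, thinning nominal rates by the busy fraction
(~10% at default rates). It returns the exact metric panel implied by the
emitted events, computed by an independent scan with the same summation
order — the acceptance check requires bit-exact agreement with the
analysis module on every stream. DSS sessions default to fewer rears
(1/min vs 2/min), shorter bouts (0.8 s vs 1.5 s) and less ambulation
(14/min vs 20/min) than water sessions, matching the direction of the
reported behavioral effects.

## Statistical gating

Outliers: a point is excluded when |x − mean| ≥ 2 SD (population SD, with
the point included, inclusive at the bound) and/or flagged by one-pass
two-sided Grubbs at α = 0.05. The population SD is deliberate: with the
sample SD no point in a group of n ≤ 5 can ever reach 2 SDs
(max |z| = (n−1)/√n), and small groups are the norm here. Grubbs is
one-pass by default (`iterative_grubbs` available); groups under 3 skip
Grubbs with a warning. Exclusion precedes analysis and every exclusion
records which rule fired.

Branching: two-sided variance-ratio F-test at the analysis α gates
t-test vs Mann-Whitney (exact Mann-Whitney up to n = 20 without ties,
asymptotic with tie correction otherwise); Brown-Forsythe (Levene on
medians) gates factorial ANOVA (type-II, Tukey pairwise on significant
effects) vs Kruskal-Wallis on the cells; repeated-measures and mixed
designs use Greenhouse-Geisser-corrected ANOVA (via pingouin). Whether
the variance gates share the analysis alpha is unstated upstream; they do
by default (`gate_alpha` overrides). Degenerate inputs (zero variance
everywhere) report p = 1 with a flag. The gate's own behavior is part of
the contract: homogeneous normal data reach the parametric branch at rate
1 − α exactly, so the acceptance check tests binomial consistency with
0.95 rather than a sharp ≥ 95% count.

## Gene-phenotype correlation

Pearson by default (ranking normalized expression against a continuous
metric; Spearman via config), computed across all animals (restricting to
treated animals is a config switch). Pairwise-complete deletion for
missing phenotypes with n recorded per gene; < 3 complete pairs is an
error; zero-variance genes are skipped and flagged. Top-k lists (k = 25)
per sign, sorted by |r|, ties broken by gene id; p from the t
distribution with n − 2 df.

## Pipeline

YAML config validated with pydantic; one global seed derives all stage
seeds, and identical config + seed reruns are byte-identical (no
timestamps enter any output; the run report records parameter echoes and
SHA-256 checksums per stage). The simulate stage ties the species
together: the planted bioset signature sits on human orthologs of 60% of
the mapped planted mouse genes, so the overlap stage has a real signal to
find. A stage failure aborts downstream stages and still writes the
partial report.

## Problem sizes

Verification runs use 1000–2000 genes, 18 lists over ≤ 1000-gene
universes, 50 open-field sessions, 100 random metasignature instances,
100,000-draw permutation nulls, and 1000–2000 simulation replicates for
the branching and type-I checks — sizes chosen so the whole suite and the
acceptance script each complete in a few minutes on one CPU while keeping
Monte-Carlo error well inside the tolerances tested.

## Known limitations

- The NB test's FDP at the default conditions sits at ~0.10 (see above);
  real analyses wanting FDR control should add one — the package omits it
  to stay faithful to the procedure it re-implements.
- The generators are deliberately simple: independent genes, a single
  shared dispersion, renewal-style behavior streams with exponential
  pauses. They fix ground truth exactly but do not emulate batch effects,
  circadian structure within sessions, or position-dependent behavior
  (no thigmotaxis/center-time zoning).
- Ortholog maps are inputs (or simulated); no ortholog inference.
- Counts only; no read-level simulation or mapping.
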