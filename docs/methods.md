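# Methods

`crossgp` re-creates, end to end and on synthetic data with known truth,
the analysis chain used to pool heterogeneous wheat breeding data from
several experimental series into one genomic-prediction training set.
This note documents the models, the generator, the numerical choices and
the limits of what the tests can show.

## The synthetic multi-series generator (`simdata`)

The generator is the study population: its defaults define the
conditions under which every downstream claim is tested.

**Genomes.** A founder pool of binary haplotypes is built block-wise:
markers fall into consecutive linkage blocks (default 20 markers); each
block has a small set of ancestral haplotypes (default 8) from which
every founder copies one, with a 2% per-allele mutation rate. Blocks are
independent, so LD is strong within and absent between blocks.
Monomorphic columns are resampled. Inbred lines arise from random
founder crosses selfed for six generations, with gametes recombining
freely at block boundaries; expected residual heterozygosity is
0.5^6 ≈ 1.6%, comfortably inside the 10% per-genotype QC threshold. The
founder pool defaults to 50 haplotypes — elite Central European wheat
pools have effective population sizes of roughly 30–80 — which makes
relatedness strong enough that kinship-based prediction and imputation
carry real information.

**Series and panels.** Several experimental series are drawn from the
one weakly structured pool (real pooled elite material does not split
into discrete clusters). Each series is genotyped on its own subset of
the master marker panel: a core of blocks shared by all series plus
series-specific blocks, every second of which is shared with the next
series. Merging therefore produces the characteristic block-wise
missingness of multi-platform SNP data. A configurable number of check
genotypes (default 5) appears identically in every series; they are what
connects series in the phenotypic model and batches in harmonization.
Per-batch random missingness defaults to 2%.

**Trials.** Phenotypes follow
`value = mean + series + BV + env + GxE + trial + rep + block + residual`
with all effects iid draws from their configured variances. The staged
design — by default 40% of a series' lines in 2 environments
(unreplicated), 30% in 4, 20% in 8 and 10% in 12 (both replicated
twice), checks everywhere — reproduces the unbalancedness of commercial
trials: many early-stage candidates with very few environments, few
advanced lines with many. Series occupy staggered two-year windows.
G×E is an unstructured (genotype × environment) deviation; there are no
environmental covariates, matching the treatment of environments as
plain random effects throughout.

**Heritability calibration.** Traits are purely additive (GBLUP's own
assumption; non-additive architecture is out of scope). Marker effects
are rescaled so the realized additive variance equals `var_g` exactly.
Given a target entry-mean heritability H², the stage-2 residual
`var_delta = var_g · n̄ · (1/H² − 1)` (n̄ = mean environments per
genotype) is split evenly between G×E and plot residual, the latter
scaled by mean replication so that the calibration stays exact under
replicated trials. Parameter-recovery tests at H² ∈ {0.6, 0.8, 0.95}
recover the target within ±0.05 on the seed average.

**What the generator does not emulate** — and hence what green tests do
not prove about real data: selection between trial stages (stages are
sampled, not selected), pedigree structure across years, genotyping
error beyond random missingness, spatial field trends, heterogeneous
residual variances, dominance/epistasis, and realistic LD decay (block
LD is rectangular). Conclusions about absolute accuracy levels transfer
only qualitatively.

## Quality control and harmonization (`genoqc`)

Per batch, genotypes with >30% missing or >10% heterozygous calls are
removed first, then markers with >90% missing or >20% heterozygous
calls, fractions always over the batch's own panel. Cross-batch strand
consistency is solved on a graph whose nodes are batches and whose edge
weights count shared (marker, genotype) pairs observed on both sides;
orientation decisions travel along the maximum spanning tree from a root
batch (the one with most genotypes; ties lexicographic). A shared
marker in a child batch is flipped when flipped concordance exceeds
as-is concordance **and** the better of the two reaches 0.9 on at least
3 shared calls; otherwise A/T and C/G (strand-ambiguous) markers are
dropped from that batch and all others keep. These two constants are
explicit substitutes for thresholds the underlying procedure leaves
unstated; they are conservative in the sense that weak evidence never
triggers a flip. Orientation is therefore defined only relative to the
nearest tree ancestor carrying the marker — a marker absent from the
root is harmonized up to a per-marker global orientation, which is all
any overlap-based method can deliver. Merging takes the per-cell
majority across batches with ties set missing, and drops markers whose
allele pairs cannot be reconciled by complementing or swapping.
Post-merge marker filters: liberal ≤80% / strict ≤30% pre-imputation
missingness (always evaluated on pre-imputation calls, also when applied
to an imputed matrix) and MAF ≥ 0.05 inclusive, het calls counting one
allele copy.

## Imputation and its validation (`impute`)

The built-in imputer is a windowed k-nearest-genotype mode filler
(defaults k = 10, window = 50 markers): within each window genotypes are
compared by allele sharing (1 − mean|Δdosage|/2 over mutually observed
markers) and each missing call takes the dosage mode of the k most
similar genotypes, ties resolved toward the nearer neighbour, falling
back to the marker mode. A genotype with fewer than 30 observed calls
in a window — typically because its batch never typed that panel block —
is compared on all mutually observed markers instead, so relatedness
substitutes for local LD exactly where local LD cannot exist. The
imputer is deterministic and desk-scale; it is not a re-implementation
of a phasing-based tool, and an external VCF-based imputer can be
bridged in through a command template instead.

Validation masks known calls and counts exact dosage matches (a
heterozygote imputed as either homozygote counts as wrong — the
strictest reading). *Blocked* masking splits markers at 70% genotype
coverage (strictly greater = low-density), and for a random 10% of
genotypes holding data for more than half of the high-density markers
hides all their high-density calls. *Random* masking hides 1% of all
non-missing cells. Accuracy is per marker: correct/masked; summary
"95/75" marks are lower-tail thresholds such that 95%/75% of markers lie
above. On inbred material, guessing uniformly between the two
homozygous states scores 0.5, which the acceptance suite verifies to
±0.02.

## Linear mixed models (`lmm`, `phenomodel`)

All phenotypic models share one REML engine for
`y = Xβ + Σ Z_k u_k + e` with iid random factors. The restricted
likelihood is profiled over the residual variance and maximized over log
variance ratios γ_k = σ²_k/σ²_e: bounded Brent for one ratio, cyclic
coordinate descent with bounded Brent per coordinate for several,
stopping when −2·logL changes by less than 1e-9 relative (flat boundary
ridges oscillate at round-off; the best visited point is kept). All
matrix work runs through the Woodbury identity on the q×q random-level
scale, never on the n×n observation scale. Ratios are constrained
positive by parametrization; estimates below 1e-8 are clamped to zero
and reported as boundary cases. Fixed factors use first-level-reference
coding with the intercept added back for reporting, so BLUEs live on the
trait scale; a greedy incremental-Cholesky repair drops dependent fixed
columns when a design is rank-deficient. For every fit the solutions
equal a dense Henderson mixed-model-equation solve at the converged
variances to 1e-8 — the engine's independent oracle in the test suite.

**Stage 1** fits each environment with genotype fixed (BLUEs) and
genotype random (variance for repeatability
r² = σ²_g/(σ²_g + σ²_e/n̄), n̄ = plots per genotype), with trial,
replicate-in-trial and block-in-replicate random whenever present.
When the genotype-fixed model would be (nearly) saturated — unreplicated
trials, residual dof < 5 — design-effect BLUPs from the genotype-random
fit are subtracted from the plots and the adjusted measurements serve as
the within-environment genotype values. Before any of this, outlier
plots are removed: per environment, conditional residuals of the
genotype-random fit are re-scaled by MAD (×1.4826), converted to
two-sided normal p-values and Bonferroni–Holm corrected within the
environment; plots with adjusted p < α (default 0.05, exposed because
the underlying method family does not fix it) are dropped. Environments
with repeatability < 0.3, then environments with mean BLUE correlation
< 0.1 to all others (pairs sharing < 5 genotypes skipped), are
discarded — repeatability first, single pass each.

**Stage 2** pools within-environment means: series fixed, genotype
fixed (BLUEs) or random (BLUPs, σ²_g), environment random;
H² = σ²_g/(σ²_g + σ²_e/n̄) with n̄ = mean environments per genotype.
The stage is unweighted — every within-environment mean carries equal
residual variance — a deliberate simplification; per-environment
precision weighting is a known refinement left out. Within-series means
fit the same model per series without the series effect. Series must be
connected through common genotypes; disconnected sets are an error, not
a warning, because their effects are not estimable.

## Kinship, diversity, GBLUP (`popgen`, `gblup`)

VanRaden kinship K = ZZ′/(2Σp(1−p)) with frequencies from the observed
dosages; mean-filling missing cells before centring zeroes their
contribution, equivalent to pairwise products over mutually observed
markers. K is never blended with an identity matrix; instead GBLUP adds
a 1e-8·trace/n diagonal jitter, keeping K itself faithful. Rogers'
distance reduces, for biallelic dosages, to mean |Δdosage|/2 over
mutually observed markers; classical-scaling PCoA double-centres −D²/2,
keeps positive-eigenvalue dimensions and scales coordinates by
√eigenvalue.

GBLUP (`y = μ + g + e`, Cov g = Kσ²_g) is fitted by REML, not by MCMC:
eigendecomposing the training submatrix reduces the restricted
likelihood to a 1-D search over the variance ratio in the rotated basis,
making the fit deterministic, fast and exactly testable; for a single
variance component the predictions agree closely with a Bayesian
posterior mean, and a sampler adds nothing testable here. Test
genotypes are predicted by the conditional expectation
K_test,train(K_train σ²_g + σ²_e I)⁻¹σ²_g(y − μ). Prediction ability is
the per-group Pearson correlation of predictions with observed adjusted
means; groups under 3 genotypes or with zero variance are undefined
(nan), never silently 0. Its ceiling is √H², which the acceptance suite
checks on the seed average.

## Experiments and scaling (`experiments`, `scaling`)

Within-series CV: 20 random 90/10 splits per series on within-series
BLUEs, with the marker panel re-filtered per series (call rate ≥ 80% of
that series' genotypes, MAF ≥ 0.05). Across-series runs train on the
pooled genotypes of a series combination and score each left-out series
separately against the across-series BLUEs, once per marker-set variant
(liberal/strict × imputed/unimputed). Combinations are chosen
D-optimally: candidate rows are intercept-plus-series-inclusion
indicators over all non-empty proper subsets, and a Fedorov exchange
(best-of-5 random starts, deterministic per seed) maximizes det(X′X).
Genotypes present in several series ("multi"-labelled checks) are
excluded from both sides of these runs, since they would leak between
training and test. Three designed scenarios hold training size constant
while varying the number of series (paired single vs multi arms with a
shared test set), the environment backing (groups 1–3, 4–5, 6–9, 10+,
test sets sampled at equal series shares, rounding down and topping up
the largest series), and the year window of the training data (1–2 vs
1–5 years before the test year; infeasible test years are skipped).

The size law `ability = α·x^(1/β)` (α, β > 0; β > 1 = diminishing
returns) is fitted per test series by bounded trust-region least squares
from a log–log initialization plus 9 jittered restarts; the curve has no
intercept and passes through the origin, and reported predictions are
clipped at 1 (an ability is a correlation) without constraining the fit.
Deviations from the curve are decomposed as
`r = μ + η_test + Σ_{j∈training}(θ_j + κ_test,j) + ε` with one
REML-estimated variance per effect group — a deterministic
groupwise-ridge fit whose estimating equations match a Bayesian ridge
posterior mode under flat hyperpriors; an MCMC variant is out of scope.
Empty or singular groups report variance 0 with a warning.

## Orchestration (`pipeline`, `io`, `analysis/`)

`PipelineConfig` (YAML-loadable, unknown keys rejected) drives
`run_pipeline`, which executes simulate → QC/merge → imputation
validation → two-stage phenotypes → kinship variants → experiments →
scaling, writing every intermediate artifact plus a manifest with seeds
and stage timings. Genotypes travel as plain VCF (GT field, 1-based
positions, per-sample series labels preserved in header lines) or
dosage CSV; all writers round-trip exactly. The numbered scripts under
`analysis/` run the same chain step by step at the study scale
(4 series × 600 genotypes × 2000 markers) and narrate what they find;
the acceptance script runs a 4 × 250 × 800 configuration so that the
complete chain, including scenarios, recomputes in a couple of minutes
on one CPU. All problem sizes are the package's own choices for a
desk-scale study; every stochastic step is seeded and reproducible.

## Known limitations

* The imputer has no phasing model; its accuracy on real array data
  would trail a haplotype-clustering tool, and the validation figures
  here characterize the synthetic LD structure, not that tool.
* Stage 2 ignores the differing precision of within-environment means.
* The harmonization flip test cannot rescue strand-ambiguous markers
  with genuinely ~50% concordance; they are dropped per batch.
* Effective population size is reported nowhere: no estimator is part
  of the chain.
* Per-marker accuracy percentiles are noisy at desk scale because many
  markers carry very few masked calls per replicate.
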