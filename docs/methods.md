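# Methods

This note records the statistical models the package implements, the
conventions and defaults it commits to, what the synthetic-data generator
does and does not emulate, and the design choices made where the design was
genuinely open.

## Paired differential expression

The screen assumes log-normal intensities with a patient-matched design:
each subject contributes one case (tumor) and one control (matched normal)
sample. For feature *i* and subject *j* the per-pair ratio is
r_ij = case_ij / control_ij on the linear scale; the summary ratio is the
geometric mean r̄_i = 2^(mean_j log2 r_ij). Reports follow the microarray
convention of magnitude-with-direction: FC_i = max(r̄_i, 1/r̄_i), direction
up/down, so a feature suppressed to 0.21× prints as "4.79, down", never as
0.21. The accompanying SD is the sample standard deviation of the per-pair
magnitudes oriented by the overall direction — an interpretive choice, since
"FC (SD)" report layouts do not pin the quantity down; the report footer
states it.

Significance is a paired t-test on per-pair log2 differences (df = n−1,
two-sided). The t-test scale is a choice: intensity ratios are closer to
log-normal, so log2 is standard. Degenerate features (zero variance of
nonzero differences) return NaN with a warning rather than a silent 0;
all-zero differences return t = 0, p = 1. BH adjustment is the step-up rule
q_(i) = min_{j≥i} p_(j)·m/j capped at 1; it is checked in tests against both
statsmodels and a brute-force rejection-threshold characterization.

FC cut-off comparisons are inclusive (FC ≥ cutoff). Two filter modes mirror
the two ways screens are reported: raw FC only, and FC plus p < α.

Hierarchical clustering of selected features uses complete linkage with
Euclidean distance on the per-feature sample vectors (scipy); features are
processed in lexicographic id order so merge ties break deterministically.

## Gene-set overlap

The overlap test is the exact hypergeometric upper tail; the one-sided
Fisher exact test on the overlap-layout 2×2 table is the identical quantity
and is exposed (with conditional odds ratio and the "sum of ≤-likely tables"
two-sided p) for contingency-style reporting.

The universe N is not derivable from the input sets and is the analysis's
main free parameter. The default is 19,000, approximately the annotated
human protein-coding gene count; with the canonical set sizes of this
problem (378 predicted targets, 109 disease genes, 7 shared) it yields
p = 0.0061, printing as 0.006. Every result object carries the universe
used, and genes outside an explicit universe set are dropped with a warning
rather than failing the run.

## Network propagation and validation

Input networks are STRING-style edge lists; combined scores are divided by
1000 to give weights in (0,1], with score ≥ 700 ("high confidence" in
STRING's convention) as the default load threshold — inclusive, and
configurable because published analyses rarely state the exact cut.
Self-loops are dropped, duplicate edges collapse by maximum weight,
zero-score rows are dropped (a zero weight would break the (0,1] weight
invariant), and all drop counts appear in the load summary.

Two propagation methods are provided behind one configuration switch:

- **naive_bayes** (default): s(g) = Σ over seed neighbours u of
  log(1 + w(g,u)). Treating each seed neighbour as an independent evidence
  source makes log-scores additive — a transparent, parameter-free
  naïve-Bayes combination of weighted seed adjacency. This is a
  reconstruction: "naïve Bayes network propagation" in the literature is not
  a single pinned-down algorithm, so the package implements the simplest
  member of the family and documents it as such.
- **rwr**: random walk with restart, F ← αW′F + (1−α)F₀, on the
  symmetrically normalized adjacency W′ = D^(−1/2) W D^(−1/2). The spectral
  radius of W′ is ≤ 1, so the iteration is a contraction for α < 1 and
  converges to the unique solution of (I − αW′)F = (1−α)F₀ (verified in
  tests against a direct solve). Defaults: α = 0.5, tol = 1e−8 (L∞),
  max_iter = 1000; the run summary records them plus the converged flag.
  Isolated nodes keep zero rows and are listed, not errors.

Ranking excludes the seeds (their scores are label leakage, not
predictions). Display order breaks score ties by gene id; evaluation uses
midranks. The AUC against the held-out disease list uses the rank-sum
formula with midrank ties — identical to counting concordant
positive/negative pairs with ties at ½ — under the closed-world convention
that every ranked non-validation gene is a negative. Genes in both the seed
and validation sets are excluded from the positives and reported separately.

Two nulls contextualize an observed AUC:

- **Label permutation** (`auc_permutation_null`): positives redrawn
  uniformly among ranked candidates. Its mean is exactly 0.5 regardless of
  the score distribution, making it the calibration null and the source of
  the permutation p-value.
- **Permuted seeds**: random seed sets of the original size, rescored and
  re-evaluated. On scale-free networks with a dense disease module this
  null sits *above* 0.5 (~0.57 under the default benchmark conditions):
  random seeds still touch hubs, and module genes are hub-like. It is the
  more conservative baseline and is reported alongside, but its mean is a
  property of the topology, not 0.5.

## Assay statistics

Comparative-Ct quantification averages replicates per sample, then
ΔCt = mean(target − reference) per group, ΔΔCt = ΔCt(case) − ΔCt(control),
relative expression 2^(−ΔΔCt). Amplification efficiency is assumed exactly
2 (no efficiency correction), so one cycle = one doubling; swapping group
labels inverts the result exactly.

Wound closure is (initial − remaining)/initial × 100 — the standard
definition; it is unit-free and rejects a remaining breadth larger than the
initial one. (Published "wounded area" formulas are sometimes printed in a
degenerate form that reduces to the remaining breadth alone; the standard
definition is implemented.) Gel contraction is the treated/control diameter
ratio, > 1 meaning less contraction than control.

Exact tests enumerate their nulls: Mann–Whitney over all C(nx+ny, nx) group
assignments for nx+ny ≤ 12, Wilcoxon signed-rank over all 2^n sign patterns
for n ≤ 15 (zeros dropped first, the standard convention), both with
midranks and a two-sided p defined as the null probability of a statistic
at least as far from its mean as observed. Larger samples fall back to
scipy's tie-corrected normal approximations. Discreteness makes the exact
tests conservative at very small n. t-tests additionally accept published
summaries (mean, SEM, n per group) so printed tables can be audited without
raw data; Welch–Satterthwaite df is computed from the SEMs.

## Synthetic data: what it emulates, what it does not

The generator produces data with the *statistical structure* the analysis
assumes, at sizes chosen for fast, well-powered tests:

- **Network**: Barabási–Albert preferential attachment (disease
  interactomes are hub-dominated; Erdős–Rényi available for null checks)
  with a planted module receiving each missing internal edge with
  probability `module_extra_density`, and uniform edge weights. Benchmark
  conditions: 500 genes, attachment 2, module 25, density 0.4.
- **Gene sets**: seed and validation sets with exact sizes, exact mutual
  overlap, and a controlled fraction drawn from the module — a 1/10-scale
  analogue of a 378-target / 109-disease-gene / 7-shared configuration.
  When the two module quotas are individually feasible but jointly exceed
  the module (they must be distinct apart from shared genes), both quotas
  are shrunk proportionally to fit and a warning is logged; sizes and the
  mutual overlap are never compromised.
- **Expression**: log2 value = feature baseline (uniform 6–12) +
  per-(feature,subject) effect N(0, σ_subject²) shared by the pair +
  condition effect ±log2(FC) on case samples of planted features (half up,
  half down) + residual N(0, σ_noise²). Defaults: 500 features, 13 subject
  pairs, 6 planted features at FC 4, σ_subject = 1.0, σ_noise = 0.3. The
  subject effect cancels within pairs, which is exactly why the paired
  design has power.
- **Ct tables**: constant reference Ct (20), control target Ct 25, case
  shifted by ΔΔCt, Gaussian replicate noise (sd in cycles) on the target
  only. Planted shifts of 1.60 and 2.12 cycles give relative expressions
  0.330 and 0.230.

Not emulated: probe-level microarray effects (RMA/DABG summarization,
probe cross-hybridization), batch and plate effects, correlated features,
annotation error in gene sets, and the literature/database biases of real
interactomes. Passing tests therefore demonstrate that the *methods* recover
known signals under their own assumptions — not that those assumptions hold
in any particular tissue dataset.

## Problem sizes and determinism

Test and acceptance runs use 200–500-node networks, 20 replicate cohorts
for AUC means, 199 label permutations and 99 seed permutations for nulls,
2000 null features for screen calibration and 100 replicates for recovery —
sizes at which every Monte-Carlo margin in the tests is multiple standard
errors wide. Every simulator is a pure function of (spec, seed); the CLI
derives per-stage seeds from one master seed, and end-to-end reruns are
byte-identical.

## Known limitations

- The naïve-Bayes scorer is one-step: genes with no direct seed neighbour
  score 0 and tie at the bottom. RWR is the choice when multi-hop signal
  matters.
- The closed-world negative convention underestimates AUC when undiscovered
  true positives rank highly.
- BH assumes independence/PRDS across features; correlated expression can
  make the FDR control approximate.
- The hypergeometric universe is a modelling choice; conclusions should be
  checked across plausible universes (the report always prints the one
  used).
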