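# Methods

This note documents the models implemented in `syndiversity`, the
assumptions behind them, what the synthetic-data generator does and does
not emulate, the numerical choices, and the known limitations. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## 1. The experimental design being modeled

A FASS proteomics experiment produces, per animal and brain region, one
*sorted* run (flow-sorted fluorescently labeled synaptosomes of one cell
type) and one matched *unsorted control* run (all membrane-positive
particles from the same precursor pool). DIA mass spectrometry yields
feature-level intensities — several precursor/fragment features per
protein — per run. Controls are pooled per brain region across cell lines
for testing, since the unsorted precursor does not depend on which Cre
line was sorted. A *synapse type* is a cell-type × region combination
(15 in the default layout: Camk2a in CX/HC/STR/Bulb, Gad2 and Syn1 in all
five regions, Dat in STR).

## 2. Per-protein enrichment model (`quantmodel`)

### Normalization

Per-run log2 medians are equalized to the median of per-run medians.
Median centering removes run-level loading/acquisition offsets and makes
all downstream contrasts invariant to per-run constants. Limitation:
under strongly asymmetric regulation (a large fraction of the proteome
changed in one direction in one run class) the median itself shifts and
a small bias of that shift's size propagates into fold-change estimates;
this is inherent to global normalization, not specific to this package.

### Two-stage linear model

Per protein, log2 feature intensities follow an additive fixed-effects
model with feature and run effects,

    y_{f,r} = mu + phi_f + a_r + e_{f,r},

fitted by least squares (features observed only once are dropped as
unestimable and recorded). The run-level abundance is a_r plus the mean
feature effect. Group least-squares means and the pooled residual
variance are then computed at the *run* level:

    log2FC = mean_{r in A} a_r − mean_{r in B} a_r,
    SE^2   = s^2 (1/n_A + 1/n_B),   df = n_runs − n_groups,

with two-sided p from the t distribution. The run level is the correct
error stratum because biological replicate variation is shared by all
features of a protein within a run; pooling feature-level residuals would
treat correlated measurements as independent and overstate the effective
sample size by roughly the feature count (measured on null simulations:
feature-level pooling produced a ~98% false-call rate where the run-level
model produces ~0.1%). With one biological replicate per run and no
technical replicates this two-stage form is the reduced case of the
standard mixed-effects formulation for this design.

An exactly zero residual variance (noise-free degenerate input) admits no
valid t statistic and flags the fit untestable; the numerical floor is
1e-12 log2² units.

### Testability and calling

A protein is testable for a contrast when it has ≥ 6 distinct features
and ≥ 12 feature measurements in every condition the contrast touches
(defaults; both configurable). Calls use a fold-change-gated BH
procedure: BH runs over the p values of proteins with |log2FC| >
log2(1.1) (strict inequality, symmetric for de-enrichment); enriched
requires adjusted p < 0.05 and a positive log2FC. The conventional
all-protein BH is available via `bh_scope="all"`. Adjustment is per
contrast. Missing feature measurements are treated as missing-at-random
and dropped; no imputation (the testability filter guards sparsity).

## 3. Membership calling (`membership`)

Membership of protein p in the proteome of type A (one region):

- **I** — enriched vs control AND not in the adjusted-significant set of
  the direct A-vs-B comparison (whether FC-gated out or p-failing);
- **II** — significantly enriched in the direct A-over-B comparison AND
  positive log2FC vs control;
- **III** — as II against a third type C.

Membership is the OR; the recorded criterion is the first satisfied in
order I, II, III (bookkeeping only). Criteria II/III require the
vs-control comparison to be testable: a protein absent from the control
comparison cannot vouch for control-side enrichment and is flagged.
Proteins quantified vs control but absent from a direct comparison are
eligible via criterion I only. The shared/type-enriched partition labels
a protein A-enriched (direct significant, positive), B-enriched
(symmetric), shared (enriched over control in both types, direct not
significant), else unassigned.

Subfield interaction contrasts, estimate = (A_sorted − A_control) −
(B_sorted − B_control), are computed inside one joint per-protein fit of
all four groups so the standard error propagates through a single design.

A caveat on monotonicity: relaxing alpha enlarges the significant set of
the *direct* comparison as well, which can break criterion I for a
protein whose direct contrast is negative and near-significant without
rescuing it via II. Membership is therefore not globally monotone in
alpha; the property test asserts the exact characterization (any member
lost under a relaxed alpha has a newly significant negative direct
comparison).

## 4. Profiles, PCA, variance partitioning (`profiles`)

The profile value of protein p in matched pair (sorted run s, control run
c of the same animal) is the median over features observed in both runs
of log2 I_{f,s} − log2 I_{f,c}. This feature-paired median is robust,
cancels fixed feature responses exactly, and is invariant to per-run
offsets already consumed by normalization. It deliberately sits outside
the contrast framework (no model variance is attached); the model-based
route exists separately through `quantmodel`. Type-averaged columns
(means over animals of a synapse type) are used for figures, networks,
and pair statistics; per-animal columns for sample-level statistics.

PCA treats columns (samples) as observations: proteins with more than a
configurable missing fraction (default 0.3) are dropped, remaining gaps
are protein-wise mean-imputed (both counts reported), components come
from a full SVD with the deterministic sign convention that each
component's largest-magnitude loading is positive.

Per-protein variance fractions for categorical covariates (cell type,
region, age, sex) are sequential sums of squares averaged over all
covariate orderings — the LMG/Shapley decomposition, computed exactly
(≤ 6 covariates) from the R² of every covariate subset via orthonormal
subset bases shared across proteins. This replaces random-effects
variance-partitioning tools with a deterministic, order-free equivalent
for balanced categorical designs. Aliased covariates (no rank added to
the rest) are flagged and reported as NaN. The covariate-level summary
uses two-sided paired t tests across proteins.

## 5. Correlation network (`conet`)

Biweight midcorrelation with tuning constant 9: observations are weighted
by Tukey biweights from the median and unscaled MAD; a side with zero MAD
falls back to Pearson centering for both sides (recorded in the value
itself being exact there). bicor is invariant under positive affine
transforms of either argument.

Network construction is restricted to proteins with complete profiles
(the filtered count is stored on the model). Signed-hybrid adjacency
a_ij = bicor_ij^β for bicor_ij > 0, else 0, with soft power β = 6.
Topological overlap

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

gives the clustering dissimilarity 1 − TOM (1 − adjacency available by
flag; which the original analyses used is not stated in such workflows'
method sections, so both are exposed).

Module detection is a static cut of the average-linkage tree. The default
cut height is 95% of the maximum merge height — branches that only join
near the top of the tree are distinct modules. This replaces dynamic tree
cutting with a deterministic, parameter-light variant; the choice was
validated on planted-module recovery (adjusted Rand index ≈ 0.9 for five
planted modules of 50 proteins across 15 types, measured by the test
suite). Clusters below 20 proteins become unassigned (label 0, the "grey"
convention); modules whose eigenproteins correlate above 0.75 are merged
iteratively; final labels are ordered by decreasing size.

Eigenproteins are the first principal component of the standardized
member profiles, unit variance across types, sign-aligned to the module
mean profile. Module–trait correlation is Pearson r with two-sided p from
t at n − 2 df; categorical traits are one-hot encoded; constant traits
are reported missing. Network export keeps edges with weight strictly
above 0.3 by default, each unordered pair once.

## 6. Pair statistics (`pairstats`)

Complex co-regulation: all within-complex Pearson correlations of
quantified subunits (≥ 4 complete paired observations) against
`n_random` random cross-protein pairs excluding within-complex pairs (a
clean null). The permutation p is the fraction of medians of resampled
random-pair sets (matched in size to the complex-pair set) at least as
large as the observed complex median.

Negative-pair screen: Pearson r over the type-averaged profiles,
two-sided t test (df = n − 2), BH across all screened pairs (raw-p mode
by flag); significant-negative requires r < 0 and adjusted p < alpha.
The candidate universe is supplied explicitly (e.g. all pairs within
protein families); an all-pairs mode is a caller decision with quadratic
cost.

Over-representation: hypergeometric upper tail of the overlap between a
query set and each gene set intersected with the universe, BH across
sets.

## 7. Sphere stereology (`spheresim`)

Sampling follows the stated geometry exactly: X ~ Uniform(0, R) (sampling
the signed axis is equivalent by symmetry), section area π(R² − X²),
expectation (2/3)πR². The calibration curve averages `n_repeats = 4`
independent means of `n_sections = 30` areas per diameter and is
monotonized by isotonic regression before inversion — sampling noise can
invert adjacent grid points and the monotone adjustment (count recorded)
guards invertibility. Inversion is monotone linear interpolation with no
extrapolation; out-of-range areas raise. An analytic closed-form mode
exists alongside the sampled, experiment-faithful default. The diameter
grid and units are caller-declared.

## 8. The synthetic-data generator (`synthdata`)

What it emulates, with defaults chosen to match the study conditions:

- **Latent structure**: per-protein baselines N(14, 1.5²) log2; planted
  modules (default 14 of 40 proteins at loading 0.9) driven by type-level
  factors; the first three module factors load on the vGat-like trait and
  the next three on the VGlut1-like trait (traits are cell-type means
  plus jitter, mimicking immunofluorescence of inhibitory/excitatory
  markers); complexes are subsets of single modules; anti-correlated
  pairs mirror one member's loading (default 0.95) and are redrawn until
  the realized latent correlation is ≤ −0.8, so the planting is
  guaranteed by construction.
- **Mixtures on the linear scale** (physical particle pooling). Sorted
  run of type t: purity · target + (1 − purity) · background, where the
  background is the mean of the other types plus a 10% contaminant
  pseudo-proteome (a seeded 10% protein subset elevated +3 log2, the
  rest depleted −3, standing in for mitochondrial/myelin carry-over so
  de-enrichment is simulable). Control run: all types at precursor
  prevalences plus the contaminant component. Defaults: purity 0.85
  (reported sorted purities run ~80–95%), prevalence 0.2 (labeled
  populations span ~0.5–50% of the precursor pool), contaminant 0.1 (a
  free parameter — unsorted-fraction contaminant composition is not
  quantified anywhere; it is a modeling device, not an estimate).
- **Quantification**: features per protein 1 + Poisson(mean − 1), mean 8
  (an exact-count mode exists for diagnostic scenarios); fixed log-normal
  feature responses (log2 sd 1); biological replicate noise shared by all
  features of a protein within a run, calibrated so the realized
  protein-level CV is the target (default 20%, the median replicate CV
  of well-behaved label-free data; the calibration is verified
  empirically by the suite); small per-measurement technical noise
  (log2 sd 0.1); logistic intensity-dependent dropout (midpoint 9,
  slope 1 in log2 units). Ages and sexes are balanced across conditions
  so variance partitioning has null covariates by default.

What it does **not** emulate: raw spectra, retention time and
chromatographic artifacts, interference between co-eluting features,
batch drift, protein-inference ambiguity, flow-cytometry scatter, or
non-spherical particle geometry. Passing the recovery benchmarks
therefore demonstrates correctness of the statistical machinery under the
stated generative assumptions, not robustness to every artifact of real
acquisitions.

## 9. Benchmark harnesses and problem sizes (`evaluation`)

Sizes are chosen to make each check statistically meaningful at desk
scale:

- *Null calibration*: 20 simulated datasets × 10 types × 1,000 proteins
  (≥ 200 sorted-vs-control contrasts), flat truth and zero purity so
  sorted and control are exchangeable; the false-call fraction among
  FC-passing tested proteins is compared with 0.05 + 3 binomial SE.
- *Power*: 200 proteins planted at 2-fold in one type, 5 animals/group,
  CV 20%, exactly 6 features (the Poisson default would leave ~44% of
  proteins under the 6-feature testability minimum at mean 6, which
  would measure the filter, not the test).
- *Membership recovery*: one region, three cell types, one planted set
  (120 of 1,200 proteins at +1.5 log2), scored under a clean diagnostic
  scenario — pure sort, no contaminant, fixed features. Under the
  contaminated default mixture, sorting genuinely enriches every
  non-contaminant protein by a small compositional margin (~+0.11 log2),
  so a planted-set truth would count real signal as error; the clean
  scenario makes the planted set the exact truth.
- *Module/trait recovery*: 10 seeds × (5 modules × 50 proteins, loading
  0.9, 15 types, 3 animals) through the full simulate → profile →
  network path; adjusted Rand index vs planted labels, and the planted
  inhibitory module must carry the largest *signed* correlation with the
  vGat-like trait (the vGat- and VGlut1-like traits are strongly
  anti-correlated across types, so the excitatory module's
  anti-correlation can rival the inhibitory module's |r|; the signed
  maximum identifies it uniquely).
- *Pair statistics*: planted complexes (6 × 5 subunits inside modules)
  vs 5,000 random pairs; planted anti-correlated pairs among random
  candidates.
- *Sphere recovery*: 100 spheres of true diameter 600 (arbitrary units),
  30 sections each, against a sampled calibration curve on a 10-point
  grid.

## 10. Known limitations

- The run-level error model ignores uncertainty from the stage-1 feature
  summarization (standard practice for this design; anti-conservative
  only when feature counts are tiny, which the testability filter
  excludes).
- Median normalization biases fold changes when regulation is strongly
  asymmetric (§2); the generator reproduces this honestly.
- The FC-gated BH procedure controls FDR within the gated set of each
  contrast; membership ORs up to three contrasts, so the false-member
  share can exceed the per-contrast level when true members are few.
- Static-cut module detection can split elongated modules at low cut
  heights or fuse correlated trait-driven modules (which then merge into
  communities — the intended behavior for trait-linked structure).
- Variance partitioning assumes categorical covariates and complete
  profiles; continuous covariates must be discretized by the caller.
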