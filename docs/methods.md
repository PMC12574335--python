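# Methods

`rootshape` analyses the quantitative genetics of storage-root shape from
binary silhouette images through to genomic prediction. This note records
the models it implements, the choices made where several formulations are
defensible, and what the synthetic study does and does not emulate.

## Shape phenotyping

A root mask is a binary raster with the crown at the top and a known
mm-per-pixel scale. Cleanup keeps the largest connected component (an
ambiguity between equal-sized components is an error, not a guess) and
fills interior holes before any area is measured, since the quantity of
interest is the area of the silhouette.

Six traits are derived per root:

* **digital biomass** — foreground pixel count x scale^2 (mm^2);
* **length** — vertical distance between the crown anchor and tip anchor,
  each the midpoint of the top/bottom foreground row span. Images are
  assumed axis-aligned (roots are photographed hanging vertically); no
  reorientation is attempted;
* **maximum width** — the largest horizontal foreground extent over all
  rows, with extent measured between outer pixel edges
  (max col − min col + 1), matching a calliper "diameter";
* **width** — the horizontal extent at 50% of the length;
* **length-to-width ratio** — ln(length / maximum width), computed exactly
  from the two quantities above;
* **tip angle** — the interior angle at the tip anchor subtended by the
  left and right contour points located 10% of the root length above the
  tip. Reference points use outer pixel edges (ties broken to the
  outermost column); for solids of revolution this matches the closed form
  2·atan(w(h)/h) to within about a degree at 0.5 mm/px;
* **root contour** — the PC1 score of the size-normalised width profile
  (below).

Width profiles are sampled at S = 101 fixed fractional depths
(t = 0, 0.01, ..., 1), enough to resolve typical root pixel heights
without oversampling. For the contour score each profile is normalised to
widths / max(width) — removing size while keeping where along the root the
mass sits — then column-centred and decomposed by SVD. The score is the
PC1 projection; its sign is fixed so positive scores accompany crown-ward
mass. One shape space is fit per dataset (accession collection) and
per-root values are projections onto it, so scores are comparable across
the population. The normalisation and the use of PC1 alone are
implementation choices; the sensitivity to using further PCs has not been
explored.

Outlier screening is single-pass: per trait, observations with |z| strictly
greater than 3.0 (z from the unfiltered mean and SD) are removed and
logged. A zero SD removes nothing; the boundary case |z| = 3.0 is kept.

## Trial model and heritability

Observations follow

    y_ijkl = mu + g_i + e_j + (g x e)_ij + b_k(j) + p_l(jk) + eps_ijkl

with environment = location-year, block nested in environment, and plot
nested in (environment, block). Two fits are produced per trait: genotype
fixed (yielding BLUEs used downstream for GWAS and prediction) and genotype
random (yielding sigma_g^2, BLUPs with prediction error variances, and
heritability). The plot term is only identified when plots hold multiple
roots; with one root per plot it is dropped with a logged warning.

REML is computed by profiling the residual variance out of the restricted
likelihood and minimising the profiled deviance over the log variance
ratios (Nelder-Mead). Each evaluation assembles the Henderson mixed-model
coefficient matrix C sparsely and takes one sparse LU factorisation, using
the identities log|H| + log|X'H^-1 X| = log|Gamma| + log|C| and
y'Py = y'y − theta_hat' W'y. This is the same estimand as an EM-REML
iteration but far cheaper at the default design (~3,400 equations), and
variance ratios are bounded away from the boundary only by the optimiser's
log-scale clip (ratios below e^-25 are reported as exact zeros).
Convergence is the optimiser's own criterion; a non-converged fit is
flagged on the result rather than raised.

Heritability is the Cullis form H^2 = 1 − PEV / sigma_g^2, with PEV half
the mean pairwise variance of BLUP differences, computed from the genotype
block of C^-1 at the converged estimates, and the result clamped to [0, 1]
(0 by convention when sigma_g^2 = 0).

Per-environment BLUEs refit the within-environment model (genotype fixed;
block and plot random) and feed Finlay-Wilkinson regression: each
accession's values regressed on the environment means, slope 1 being
average sensitivity. By default the complete-replication subset of
accessions defines the environment means.

**Replication note.** The environment variance is estimated from only four
environment levels at the default design, so a single simulated trial
carries a relative sampling SD near 80% for that component. Recovery
checks therefore average 30 independent trial simulations, a problem size
chosen so each component's mean estimate is measurably within +-25% of
truth.

## Population structure

* **Marker QC** implements the GBS rules as configurable filters: optional
  per-call depth/GQ minima (failing calls become missing), at least five
  individuals per homozygous class, and removal of markers whose modal
  genotype frequency strictly exceeds 1 − 5/N. At equal counts the
  hom-class rule subsumes the frequency rule (the largest modal share with
  both hom classes at 5 is exactly 1 − 5/N), so the latter only bites when
  configured separately.
* **LD pruning** scans markers in position order and drops a marker whose
  dosage r^2 with any retained marker within the 50-kb window exceeds the
  cutoff (default 0.02). r^2 is the squared Pearson correlation of dosages
  (composite LD; GBS data are unphased). The step parameter of
  sliding-window tools is accepted for config compatibility; the positional
  scan is its dense limit.
* **PCA** is SVD of the mean-imputed, column-centred dosage matrix;
  variance shares are eigenvalue fractions of the total.
* **Admixture** maximises the binomial mixture likelihood
  L = sum_ij [g ln(qf) + (2−g) ln(1−qf)] by multiplicative EM updates of Q
  and F, with three random restarts by default (EM is multimodal) and a
  monotonicity guarantee on every path. Model choice uses entry-masked
  cross-validation: genotype cells are partitioned into folds, each fold
  is held out of the likelihood, and held-out cells are scored by binomial
  deviance against 2·QF; k minimising the mean error is selected.
* **Distances and trees**: Nei (1972) D = −ln(Jxy / sqrt(Jx Jy)) over
  biallelic frequencies; infinite distances (opposite fixation everywhere)
  are capped at a large finite sentinel so neighbor-joining remains
  defined. NJ is Saitou-Nei with the standard Q criterion, ties broken
  toward the lowest index pair, and negative branch lengths clamped to zero
  with the deficit moved to the sister branch (path lengths preserved);
  additive matrices are reproduced exactly.
* **Fst**: the default estimator is Nei Gst as a ratio of sums —
  Ht = 1 − pbar^2 − qbar^2 from the unweighted pair mean frequency,
  Hs = mean within-group expected heterozygosity — which is hand-checkable
  (p = 0.2 vs 0.8 gives 0.36) and mirrors the distance machinery. Between
  two Balding-Nichols demes with divergence F this statistic converges to
  F/(2−F), not F; a Hudson-type estimator (sample-corrected numerator,
  ratio of sums) is provided and is the one used in recovery checks against
  the simulator's divergence parameter. A small-sample corrected Gst
  variant (unbiased gene diversity within groups) sits behind a flag.

## GWAS

Kinship is VanRaden's K = WW' / (2 sum p(1−p)) on 2p-centred dosages, with
monomorphic markers skipped; K-LOCO recomputes K per chromosome with that
chromosome excluded. The scan is EMMAX-style: the null variance ratio is
estimated once per trait (per chromosome for LOCO) by REML on the spectrum
of K, with the ratio optimised on the log scale in [−10, 10] to 1e-10;
each marker is then tested by GLS in the eigen-rotated space with a Wald t
test (scale re-estimated per marker), which matches a dense GLS solve at
the null covariance to machine precision and collapses to ordinary
regression when sigma_g^2 = 0. Markers collinear with the covariates are
skipped with a log entry. The first genotype PCs are available as optional
fixed covariates.

Inflation lambda is the no-intercept regression slope of sorted observed
−log10 p on the medians of the uniform order statistics. Bonferroni
thresholds are −log10(alpha/m). Per-marker variance explained is the
single-marker approximation 100 · beta^2 Var(x) / Var(y), capped at 100 —
an explicit approximation, since no exact definition is canonical across
association tools.

Consensus QTL calling accepts any number of labelled (model, panel)
tables: a marker passes with significance in at least two models within a
panel, or in at least one model of each of two panels; passing markers
within 100 kb on a chromosome merge transitively into one call (the radius
motivated by treating markers ~82 kb apart as a single locus), whose
reported score/PVE are means over the supporting model entries. The output
is invariant to table order.

LD decay bins pairwise r^2 by distance; the block-size statistic is the
first bin midpoint where the monotone non-increasing envelope of the
binned means drops below the target r^2 (default 0.1).

## Genomic prediction

RR-BLUP solves u = (W'W + lambda I)^-1 W'(y − ybar) with
lambda = sigma_e^2 / sigma_u^2 from REML on the spectrum of WW', computed
through the equivalent n x n system so cost scales with accessions; the
GBLUP identity (K = WW'/c, ridge lambda/c) is retained as an independent
algebraic route and agrees to machine precision at a shared lambda.
Cross-validation repeats an 80/20 accession split (default 50 replicates;
the pipeline uses 20), fits on the training set, and reports the mean
Pearson correlation r between predicted GEBVs and observed test phenotypes
with r^2 = r-squared, plus the SE over replicates.

Candidate genes are those whose bodies intersect the closed interval
+-500 kb around a QTL position (gene-body intersection, not gene start;
marker-anchored, window configurable). GO enrichment is a one-sided Fisher
exact test per biological-process term on the target/background 2x2 table,
ranked by p with no multiple-testing correction — deliberately plain
Fisher without topology weighting, and labelled as such.

## Synthetic study

The generator provides ground truth for every stage:

* **Genotypes**: Balding-Nichols — ancestral frequencies Uniform(0.05,
  0.95), population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F), ancestry
  rows Dirichlet(alpha), dosages Binomial(2, q·f); marker positions
  uniform per chromosome. Missing calls can be injected at a configurable
  rate (default 0).
* **Phenotypes** (`simulate_phenotypes`): the trial model with iid normal
  draws per random term at configured variances; the genetic value is the
  causal-marker sum plus an iid polygenic draw. Defaults are a strong
  genotype signal (sigma_g^2 = 1) against 0.25 for every other component,
  on a 4-environment x 3-block RCBD with one plot per accession-block and
  six roots per plot — the regime in which shape heritabilities come out
  at 0.9 or greater.
* **Root images** (`simulate_shape_study`): two latent genetic axes, log
  length and log width, carry the causal QTL plus a marker-encoded
  polygenic background (so additive signal is visible to genomic
  prediction); the shape family (globose / cylindrical / conical /
  taproot, raised-cosine / capped-constant / linear / power-law width
  profiles) follows the genetic length-width ratio, squat roots being
  globose and elongated ones unswollen taproots. Per-observation latents
  add environment, G x E, block, plot and root noise on the log scale, and
  each root is rasterised from its analytic profile (rows with positive
  sub-pixel half-width receive one pixel pair so tapering tips reach their
  analytic depth; rendered areas match the profile integral within 2% at
  0.5 mm/px). Digital biomass receives an extra multiplicative lognormal
  noise factor (SD 0.45) so size is genuinely harder to predict than
  shape, mirroring a trait that integrates many non-genetic influences.

What the generator does **not** emulate: real segmentation artefacts
(lateral roots, soil, lighting), linkage maps with recombination-driven LD
(structure-driven LD only), dominance or epistasis, GBS depth/quality
noise beyond optional tags, spatial field trends, and the real panel's
trait distributions (defaults span the shape families rather than matching
any particular crop's moments). Passing recovery tests therefore show the
estimators are correct under their assumed models at realistic sizes, not
that field data meet those assumptions.

## Numerical choices and limitations

* Variance ratios live on a clipped log scale; estimates at the lower clip
  are reported as exact zeros. Negative NJ branch lengths are clamped with
  sister transfer. Nei infinities are capped. PVE is capped at 100%.
* The admixture EM can converge to local optima; restarts mitigate but do
  not eliminate this, and CV error at large k inherits that noise.
* At the demo problem size (120 accessions, 600 markers) ridge-regression
  accuracy is capped near 0.65 even for noiseless additive latents, so the
  end-to-end contrast between shape and biomass prediction is qualitative,
  not a reproduction of any published accuracy.
* The mixed model assumes homoscedastic residuals across environments and
  ignores any guard-row or partial-replication structure; records are
  treated as ordinary plots.
* Default problem sizes throughout (the demo study, 30-seed recovery
  averages, 10-seed calibration suites) were chosen so each check is
  statistically meaningful at desk scale on one CPU.
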