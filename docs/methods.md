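# Methods

This note documents the statistical and image-analysis procedures gliastat
implements, the assumptions behind them, and the choices made where the
procedures left room for judgement.

## Differential expression and t-scores

Counts for gene *g* in cell *c* are modelled as negative binomial with a
log link,

    y_gc ~ NB(mu_gc, phi_g),        Var = mu + phi * mu^2
    log mu_gc = log(N_c * f_c) + x_c' beta_g

where `N_c` is the cell's library size, `f_c` its TMM normalization factor
and the design is `~ disease.status + sex + age + cdr` (disease coded
Ctrl = 0 / AT = 1, sex F = 0 / M = 1, age and cellular detection rate
standardized).  The disease effect is tested per gene by a likelihood-ratio
test of the full model against the disease-dropped model; the p-value uses
the chi-square reference with 1 df.  The per-gene **t-score** is

    t_g = sign(log2FC_g) * sqrt(LR_g)

which is asymptotically standard normal under the null — genes with large,
consistent expression changes get large |t|, and the sign follows the fold
change.  This signed-root definition is what makes the downstream gene-set
average interpretable against a permutation null.

**Fitting.**  All genes are fitted simultaneously by batched iteratively
reweighted least squares (working weights `mu/(1 + phi*mu)`), converging
when the change in log-likelihood is below 1e-8 (relative), max 100
iterations.  Genes with zero counts everywhere are dropped (logged);
non-converged genes are excluded from the t-score table with a logged count.
The LR statistic is floored at 0.

**Dispersion.**  phi_g is estimated per gene by maximizing the Cox-Reid
adjusted profile likelihood (the plain ML estimate is biased low because the
mean coefficients are estimated from the same cells; the adjustment
subtracts `0.5*logdet(X'WX)`), then shrunk halfway toward the common
all-gene estimate on the log scale:

    phi*_g = exp( 0.5*log phi_g + 0.5*log phi_common )

The 50/50 log-scale shrinkage stabilizes small-sample fits while keeping
per-gene heterogeneity; the log scale was chosen because dispersions are
ratio-scaled quantities.  Bounds: phi in [1e-4, 20].

**TMM.**  The normalization factor of each cell against the reference cell
(the one whose upper-quartile expression is closest to the mean upper
quartile) is the inverse-variance-weighted mean of per-gene log2 ratios
after a double rank-based trim — 30% from each tail of the log-ratios (M)
and 5% from each tail of the abundances (A), the published defaults.
Factors are rescaled to geometric mean 1, so sequencing depth stays in the
library size and the factor carries only compositional differences.  A cell
with zero total count is an error naming the cell.

## Gene-set permutation enrichment

A set's observed statistic is the arithmetic mean of its members' t-scores
(members absent from the universe are dropped with a logged count; the
post-intersection size is used everywhere).  The null distribution is the
same average over size-matched sets drawn uniformly **without replacement
from the full universe** — a competitive test; tested-set members stay
eligible.  With `n_perm = 10,000` draws (default), the upper-tail p-value
uses the permutation-exact convention

    p = (1 + #{null >= observed}) / (1 + n_perm)

so it is never exactly zero, and ties count as exceedances (conservative).
Bonferroni multiplies by the number of sets tested in the same invocation,
capped at 1.  For small universes (`C(n, k) <= 1e6`) the exact null can be
enumerated exhaustively; the Monte-Carlo path is validated against it.
Null mean and SD are recorded per set for mean ± 2 SD bar summaries, and a
dotplot summary (per-gene z of log1p depth-normalized expression, averaged
per disease group, plus percent of cells expressing) accompanies the test.
Genes with zero expression variance get z = 0 with a flag.

## Synthetic single-nucleus counts

The generator is the model's inverse: per-gene baselines `beta0 ~ U(-2, 3)`
(natural log, relative to the mean library size — mean counts roughly 0.14
to 20 per cell, snRNA-seq-like sparsity), log-normal library sizes
(meanlog log 5000, sdlog 0.35) so TMM has real work to do, NB dispersion
phi = 0.5, and a log2 fold change spiked into named gene sets for the
disease group.  Covariate coefficients are drawn per gene as `N(0, sd)`
with configurable sds (defaults: sex 0.2, age 0.1, cdr 0.3) — a coefficient
shared by all genes would be a pure per-cell scaling absorbed by the
library-size offset and would exercise nothing.  The detection-rate
covariate enters generation through a latent per-cell propensity; the
covariate table reports the *realized* cdr (fraction of genes detected),
which is what the model adjusts for, so the adjustment faces the same
noisy proxy it would in real data.

What the generator does **not** emulate: doublets, ambient RNA, batch
structure, gene-gene correlation, zero inflation beyond NB, and any real
biological covariance between covariates and disease.  Calibration and
power results on it therefore show the machinery is correct, not that real
cerebellar microglia data would behave this way.

## Synthetic co-culture scenes

Scenes are 512 px at 0.62 um/px (~318 um field of view): DAPI nucleus
disks (r = 4 um), CFSE microglia (isolated 9-um disks, or clusters drawn
as a disk region of the requested area partitioned among the member
nuclei), vinculin over the cell body, RELB painted with a
nuclear:cytoplasmic ratio of 3.0 in translocated cells and 0.5 in resting
cells (inactive RELB is cytoplasm-sequestered), and a beta3-tubulin
neurite network of smooth random spline curves ~2 px wide.  Gaussian noise
(sd 2) is added everywhere.  Damage erases a configured fraction of
neurite pixels inside damaged-cluster ROIs (core + 20 um border),
uniformly at random — emulating fragmentation rather than clean
retraction.

The neurite density default is 700 curves/mm^2.  The damage score is a
*median over the branches inside one ROI*, so it needs enough branches to
be statistically stable; a sparse network makes the score noise-dominated
and no classifier could use it.  A dense carpet is also what differentiated
neuronal cultures look like.

## Imaging measurements

* **Segmentation** — global Otsu (overridable) on DAPI, hole filling,
  minimum size 10 um^2, watershed splitting seeded at distance-transform
  peaks at least 4 um apart.  Cells grow from each nucleus into contiguous
  above-threshold CFSE pixels; contested pixels go to the geodesically
  nearer nucleus; a nucleus with no surround becomes its own cell, flagged.
* **Form factor** — `4*pi*area/perimeter^2` with the Crofton 4-direction
  perimeter estimator on masks; naive pixel-edge counting overestimates a
  circle's perimeter by ~27% and would break the circle = 1 criterion.
  Single-pixel masks are rejected.
* **Intensities** — per-channel scalar background (secondary-antibody-only
  control) subtracted pixel-wise and floored at 0 before MFI and
  integrated intensity (sum x pixel area).  Nuclear translocation is the
  nuclear/cytoplasmic MFI ratio; positive means strictly above 1.0
  (parameter); cells with empty cytoplasm or nonpositive cytoplasmic MFI
  are excluded and logged.
* **Clusters** — cells within 10 um (parameter) merge; a group is a
  cluster iff union area > 4,000 um^2 AND >= 5 cells; ROIs are the core
  dilated by 20 um.  Detection is order-invariant and idempotent.
* **Neurites** — the in-ROI tubulin mask is skeletonized and decomposed
  into branch segments between endpoints/junctions (adjacent junction
  pixels merged into one node, as skeleton-graph tools do; diagonal steps
  weigh sqrt(2)).  Terminal spurs shorter than 3 um are pruned —
  rasterization junk — while isolated fragments are kept, and a
  single-pixel fragment counts as one pixel of length, since fragment
  shortness is exactly the damage signal.  The score is the median branch
  length divided by the ROI area; an ROI at or below half the control
  density is damage-associated (boundary inclusive).  The control is the
  median density over area-matched disk ROIs placed outside all expanded
  cluster ROIs.

## Flow cytometry and qPCR

Event tables are plain per-event intensity frames; gates are explicit
thresholds (a helper derives the 99th percentile of a matched negative
control).  Phagocytosis = % positive minus the cytochalasin-D control,
floored at 0; beads per cell = population MFI / single-bead MFI, with both
the phagocytic-subpopulation and all-cells MFI usable as numerator;
highly phagocytic means strictly more than 2 beads.  Relative growth is
inverse MFI normalized to the 24 h point (CFSE halves per division).
Apoptosis gating is quadrant classification on Annexin V x PI.  qPCR fold
changes use 2^-ddCt with technical replicates averaged arithmetically, an
assumed amplification efficiency of exactly 2, no outlier rejection, and
2^-dCt values also emitted; samples missing the reference gene are skipped
with a warning.

## Problem sizes used in the checks

Calibration runs 2,000 genes x 100 cells/group with 200 random 20-gene
sets at 10,000 permutations; power/recovery runs 20 replicates of a
1,000-gene universe x 200 cells/group with one spiked and one matched null
set each; imaging ground truth uses 10 scenes (5 seeds x damage fractions
{0, 0.6}).  These sizes give the binomial/QQ tolerances quoted in the
tests while keeping a full run in minutes on one core.

## Known limitations

* The NB GLM uses one-step dispersion estimation (Poisson means ->
  CR-adjusted ML -> refit), not alternating to convergence, and no
  abundance-dependent dispersion trend.
* The permutation null ignores inter-gene correlation (as does the
  procedure it implements); correlated sets will be anti-conservative on
  real data.
* Imaging operates on 2-D (max-projected) scenes; no PSF, no 3-D
  segmentation, no machine-learned models.
* The damage rule inherits the median's instability when an ROI holds only
  a handful of branches; densities and the spur-prune length are exposed
  as parameters.
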