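# Methods

`sxt-celltyper` re-implements, as a tested pipeline on synthetic data, a
subcellular feature-based strategy for typing pancreatic islet cells from
soft X-ray tomography (SXT): dense-core secretory vesicles are segmented
from linear-absorption-coefficient (LAC) volumes, each vesicle is summarised
by eleven LAC-histogram parameters plus its equivalent diameter, and these
per-vesicle features drive cohort statistics, a grouped supervised
classifier of vesicle identity (glucagon vs insulin, hence α vs β cell), and
interpretation via clustered permutation importance and UMAP embeddings.

The reconstructed tomograms behind the original cohort are not publicly
deposited, so the package ships a first-class synthetic-cohort generator
whose defaults encode the published cohort summaries. Everything downstream
is exercised against those phantoms.

## The synthetic cohort

### Study conditions (generator defaults)

Eight α cells and seven β cells. Per class, cohort-level summaries (mean ±
SD unless noted):

| quantity | α (glucagon) | β (insulin) |
|---|---|---|
| cell volume (μm³) | 579 ± 247 | 1191 ± 277 |
| nuclear occupancy (% of cell) | 21 ± 5 | 10 ± 3 |
| vesicles per cell | 1337 ± 480 | 2099 ± 710 |
| pooled vesicle diameter (nm) | 194 ± 49 | 157 ± 35 |
| diameter bin masses <120 / 120–180 / >180 nm | 1% / 50% / 49% | 4.5% / 80% / 15.5% |
| pooled per-vesicle mean LAC (μm⁻¹) | 0.365 ± 0.04 | 0.328 ± 0.03 |
| between-cell SD of the cell means: LAC (μm⁻¹), diameter (nm) | 0.03, 21 | 0.02, 13 |
| within-vesicle voxel-LAC SD (μm⁻¹) | 0.012 ± 0.005 | 0.007 ± 0.003 |
| cytosol / nucleus / mitochondria LAC (μm⁻¹) | 0.263 / 0.24 / 0.357 (± 0.02–0.03) | 0.237 / 0.21 / 0.335 |

Voxel size defaults to 35 nm (valid 30–45 nm, the instrument's range).
Default seed 20240518.

### Fixed-effects cohort realization

With only 7–8 cells per class, freely drawn cell-level effects make the
*realized* pooled summaries wander by more than the tolerances the pipeline
is expected to recover (e.g. cohort-mean LAC moves by ±0.01 μm⁻¹ at n = 8
for a between-cell SD of 0.03). The generator therefore treats the cohort
as the study itself (a fixed-effects reading):

* Per-cell LAC and diameter offsets are realized as **normal scores** (Blom
  quantiles of the standard normal, scaled to the between-cell SD),
  randomly assigned to cells and centred with vesicle-count weights. The
  cohort's between-cell spread is pinned exactly, the vesicle-weighted
  pooled mean sits at the calibration target, and the most extreme cell
  sits at the typical |z| for the cohort size (≈1.4 SD at n = 8) rather
  than wherever eight Gaussian draws happen to land.
* Nuclear-occupancy draws are centred at the class mean with their SD
  pinned.
* Cell volumes and vesicle counts are truncated-normal draws (±2.5 SD);
  counts are capped at 8 vesicles/μm³ of cytosol so hard-sphere placement
  cannot dead-end. The cap is applied before counts are used as
  calibration weights.

A consequence worth knowing: quantities *not* pinned (pooled skewness,
per-cell cytosol LAC, …) still fluctuate seed to seed; pinned ones (pooled
means, bin masses, occupancy means) do not, up to measurement noise.

### Diameter law

No single two-parameter family satisfies the five pooled diameter targets
(mean, SD, three bin masses) for the insulin class — a truncated lognormal
matched to the moments puts ~13% of mass below 120 nm where the cohort
shows 4.5%. Calibration therefore tries a truncated lognormal first and
falls back to a **two-component truncated-normal mixture** (five
parameters), fitted by penalized least squares with a deterministic
multistart. Bounds are the 100–500 nm retention window.

Between-cell diameter shifts are folded into the calibration: the pooled
model is the count-weighted average of the per-cell mixtures (component
means shifted by each cell's realized offset, truncated once at the
window), evaluated with closed-form truncated-normal moments. The
calibration is re-run per cohort against the realized offsets, so the
pooled summary of *these particular cells* hits the targets, not just
their Gaussian average. Infeasible targets raise a calibration error
listing the residuals. Tolerances: mean ±3 nm, SD ±4 nm, each bin mass ±2
percentage points at 10⁵ draws.

### Sub-vesicular LAC law

Within a vesicle, voxel LAC = per-vesicle base level + a linearly
decreasing radial component + i.i.d. Gaussian voxel noise:

* base ~ class pooled mean + cell offset + within-cell N(0, σ_w), with
  σ_w² = pooled² − between-cell² (0.0265² for α, 0.0224² for β);
* the per-vesicle total voxel SD s is drawn from the class law
  (0.012 ± 0.005 / 0.007 ± 0.003 μm⁻¹, truncated ≥ 0.002);
* a fraction f = 0.7 of s² is carried by the radial term (slope
  √f·s/√0.0375 per unit r/R, mean-zero over the ball so the vesicle mean
  stays at base), the rest by noise.

This construction makes the maximum-LAC voxel sit in the inner half-radius
(>95% of vesicles), gives the pooled per-vesicle histograms a mild positive
skew and negative excess kurtosis, and reproduces the empirical ordering of
class effect sizes across the 11 parameters: maximum LAC separates the
classes most (it compounds the level gap with the spread gap), minimum LAC
least. None of these three behaviours was fitted; they emerge from the
radial model.

### Voxel phantoms

A cell is a sphere of the drawn volume holding a spherical nucleus
(occupancy-derived volume, random offset), noisy cytosol at the cell's
cytosol LAC (voxel noise SD 0.01 μm⁻¹), optional mitochondria blobs
(off by default; nothing downstream consumes them), and hard-sphere-placed
vesicles (rejection sampling on a uniform grid hash; placement failure
raises). Each dense core is wrapped in a 2-voxel boundary shell at LAC
0.17 μm⁻¹ — the membrane/lumen halo; sub-vesicular LAC falls from the core
centre outward and the periphery is the least dense part of the organelle.

The halo is also what makes threshold segmentation well-posed on the
phantom: the published cytosol LAC (0.237–0.263 μm⁻¹) lies *inside* the
vesicle segmentation windows, so on a haloless phantom the entire cytosol
joins the in-window mask and everything merges. With halos, the cytosol
becomes one giant in-window component (discarded by the 500 nm size
filter) and every core is isolated. Two validity constraints follow:
halos must keep (halo + 2 voxels) clear of the cell and nucleus boundaries
(a halo touching a boundary traps an in-window cytosol sliver as a false
component), and the cytosol cell-mean draw is floored at 0.21 + 1.9 × the
voxel-noise SD (a cytosol straddling the window floor fragments into
spurious components). The floor slightly truncates the lower tail of the
β cytosol LAC distribution. The original study did not face either regime
because its segmentation was manual and morphology-guided.

Label legend: 0 background, 1 cell (cytosol + vesicles), 2 nucleus,
3 mitochondria. Volumes are written as multipage float32 TIFF plus a uint8
label TIFF and a JSON sidecar with the voxel size.

### Feature-table mode

`generate_vesicle_features` skips rasterization: each vesicle's voxel count
follows deterministically from its true diameter at the configured voxel
size, radial positions are sampled from the ball density, and the eleven
LAC statistics are computed from that sampled voxel list with the *same*
estimator used on segmented voxels. Statistics are never drawn marginally,
so the strong collinearity between the level parameters (min … max) that
the importance analysis must handle is preserved.

## Vesicle extraction

Segmentation is 26-connected component labelling (configurable to 6) of
voxels inside the LAC window, within the cell mask, excluding nucleus and
mitochondria. The window is half-open (lo, hi]: the lower threshold is the
boundary *above* background. Class windows: insulin 0.21–0.46, glucagon
0.24–0.50 μm⁻¹; the blinded default is their union 0.21–0.50 so that no
identity information leaks into classification. Components are filtered by
equivalent-sphere diameter d = voxel · (6n/π)^(1/3): below 100 nm discarded
(synaptic-like microvesicles), above 500 nm excluded as fused clusters
(excluded, not split). Note the estimator is volumetric: an elongated
cluster *spanning* more than 500 nm is excluded only once its union volume
exceeds that of a 500 nm sphere.

Per-vesicle statistics: linear-interpolation quantiles; sample (n−1) SD;
Fisher–Pearson skew (g1) and excess kurtosis (g2); mode = centre of the
most populated 0.005 μm⁻¹ histogram bin anchored at zero, ties to the
lowest bin (LAC is meaningful to ~3 decimals); iqr = q75 − q25 exactly.
Records with fewer than 3 voxels or zero spread report skew/kurtosis 0 and
a degenerate flag. The quantile chain and iqr identity are asserted on
every extracted table.

Whole-cell metrics come from the masks: volumes = voxel counts × voxel
volume, occupancies as percentages of cell volume, cytosol = cell − nucleus
− segmented vesicles − mitochondria for the compartment LAC means. Halo
voxels count as cytosol, which biases the measured cytosol LAC downward by
roughly 0.005–0.01 μm⁻¹ at default vesicle densities — a known phantom
artifact, irrelevant to every pipeline decision.

## Cohort statistics

Two-group comparisons use Welch's t-test (Satterthwaite df, two-sided);
multi-group panels use one-way ANOVA with Bonferroni-adjusted pairwise
comparisons (p × number of comparisons, capped at 1). Effect size is η²,
the squared correlation ratio (between-class SS over total SS) computed on
pooled vesicles with class = vesicle type. Stars: * p<0.05, ** p<0.01,
*** p<0.001, † p<0.0001.

## Identity classification

Features: the 11 LAC parameters + diameter. Whole-cell morphology (volume,
occupancy) is deliberately excluded — it would let the model shortcut
vesicle identity via cell size. The α/glucagon class is the positive class
in all reported metrics.

All n_α × n_β leave-one-α-one-β-out combinations are enumerated (56 for
8+7). Per combination and model family, hyperparameters maximise mean
accuracy under Leave-One-Group-Out CV over the *training* cells (a group =
one cell's vesicles; folds whose training side degenerates to one class are
skipped with a warning), the winner is refit on all training vesicles, and
accuracy/precision/recall/F1/ROC-AUC are scored on the pooled vesicles of
the two held-out cells. Cell identity is the strict majority of a cell's
predicted vesicle labels; exact ties are flagged indeterminate rather than
coin-flipped. A leakage audit asserts on every combination that no held-out
vesicle id reaches tuning or training.

Model families and searches:

* logistic regression — pipeline with a StandardScaler fitted on training
  folds only; grid C ∈ {0.01, 0.1, 1, 10};
* random forest — 60 trees; grid max_depth ∈ {None, 8} at
  min_samples_leaf = 2;
* XGBoost — 60 rounds, hist; 25 seeded random-search draws (the 10 + 15
  evaluation budget of a Bayesian-optimization run) over log-uniform
  learning rate 0.03–0.3, depth 2–6, subsample and colsample 0.6–1.
  Candidate scoring goes through the native train API with per-fold
  DMatrix reuse; the winner is refit through the sklearn wrapper.

Grids are config-overridable. The shipped defaults are deliberately small:
the full default run is 168 LOGO-tuned models and is sized to finish in
minutes on one CPU. Held-out cells are always scored on all their
vesicles. The training side is subsampled in two tiers: LOGO tuning sees
50 vesicles/cell (hyperparameter selection is robust to subsampling), and
the selected model is refit on 250 vesicles/cell before held-out scoring.
The refit tier matters at the hard end: on the most adversarial held-out
pair (the extreme-LAC α cell against the extreme-LAC β cell, whose
LAC-level features invert), tree-model accuracy rises steadily with
training size, and a final fit starved to the tuning subsample can sit at
chance where a 250/cell fit does not.

Determinism: one root seed expands per (combination, family) in a fixed
order; RF/LR runs are bit-reproducible, XGBoost given a fixed seed and one
thread.

## Interpretation

Permutation importance = baseline held-out accuracy minus mean accuracy
after shuffling one feature column (default 10 repeats). Because the level
parameters are nearly collinear, features are first grouped by average-
linkage hierarchical clustering on 1 − |Pearson r| cut at 0.3 (both
configurable); the representative of a cluster is its member with the
highest mean |r| to its cluster mates, ties broken alphabetically so the
choice is invariant to column order; constant features are isolated with a
warning. Reported importances average the combinations whose held-out
accuracy exceeds 75%. For display, importances are conventionally rescaled
to the largest observed value.

UMAP embeddings use the canberra metric (its per-coordinate scaling suits
features on different numeric scales): vesicles with n_neighbors = 50,
min_dist = 0.5; whole cells with n_neighbors = 4, min_dist = 0.2. All
columns except skew and kurtosis are z-scored first (those two are already
dimensionless shape parameters). UMAP is stochastic, so a seed is
mandatory and figures are treated as qualitative; the quantitative check is
a clustering-agreement property (a 2-means split of the vesicle embedding
agrees with true identity in >60% of points), never coordinates.

## Pipeline

`run_pipeline` executes generate → (extract) → stats → classify → interpret
from one JSON/YAML config with a single root seed, writes CSV/JSON
reports, and records a manifest (config snapshot, seeds, per-stage status,
output SHA-256). Stages whose outputs exist with matching hashes are
skipped on re-run. The CLI (`sxt-celltyper generate|extract|stats|
classify|importance|embed|run`) is a thin layer over the library.

## Problem sizes used by the shipped checks

The acceptance script and the slow tests run the default cohort with voxel
phantoms at 45 nm (within the instrument's 30–45 nm range; ~2×10⁴ vesicles
over 15 cells) and the classifier sweep with 50 training vesicles per cell.
Both are package choices that keep a full run in the tens of minutes on a
single CPU; pooled recoveries and evaluation aggregates are insensitive to
them at the tolerances checked.

## What passing tests do and do not show

The phantoms emulate class-conditional *distributions* of real cohort
summaries, not tomograms: there is no projection/reconstruction physics,
no missing wedge, no capillary geometry, no segmentation ambiguity beyond
Gaussian voxel noise, spherical geometry everywhere, and independent cell
offsets for LAC and diameter. Parameter-recovery results therefore
validate the *pipeline's bookkeeping and estimators*, and the classifier
results validate the *evaluation machinery and its honest grouping*, under
distributional assumptions matched to the published cohort — they are not
evidence about new real data. Known limitations worth restating: measured
cytosol LAC is biased low by halo voxels; vesicles just above the 100 nm
floor can rasterize below it and be dropped (<1% of insulin vesicles at
45 nm); the β cytosol LAC lower tail is truncated by the window-floor
constraint; Table-level per-cell diameter means are not separately matched
where they conflict with the pooled values (the pooled values win).
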