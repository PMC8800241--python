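# Methods

`gliaclust` maps where microglia and astrocytes are activated in
immunofluorescence sections without hand-drawn regions or per-cell
annotation. The core idea: activation changes cell morphology in a
stereotyped way (brighter staining, enlarged rounder somata, fewer and
shorter processes, denser spacing), so windows of activated tissue are
*morphological outliers* relative to control tissue, and genuine
activation is *spatially coherent* while noise is not.

## Pipeline

1. **Feature extraction.** Each single-channel plane (max-intensity
   projection) is background-subtracted, despeckled (3×3 median), and for
   GFAP additionally contrast-stretched; pixels outside the tissue ROI
   are cleared. A 100 µm × 100 µm window slides across the section with
   50% overlap (stride 50 µm, origin-anchored; windows crossing the image
   edge are dropped; the per-axis count is ⌊(L−w)/s⌋+1). Foreground is
   defined by the Phansalkar local threshold on intensities normalised to
   [0, 1]:

       v > m · (1 + 2·e^(−10m) + k·(s/r − 1)),   k = 0.25, r = 0.5,

   with m, s the local mean/sd in a radius-60 px neighbourhood. Per
   window we measure Mean, IntDen (= mean × foreground pixel count) and
   Area; box-counting fractal dimension D (box edges 2–64 px, slope of
   log N(ε) vs log 1/ε); skeleton branch statistics after thinning
   (branches, total branch length with √2 diagonal weighting, junction
   clusters, triple points, end points, slab pixels); total foreground
   perimeter (Crofton, 4 directions); and soma-derived features (count,
   mean area, mean circularity 4π·area/perimeter², mean nearest-neighbour
   distance between soma centroids) from a simplified segmentation chain:
   opening (disk r = 2) → white top-hat → threshold (global iso-data for
   IBA1; Phansalkar k = 0.15 for S100B) → size filter (25 px microglia,
   30 px astrocytes at 1.5 px/µm). Thresholds are additionally required
   to clear a robust noise floor (median + 4·MAD·1.4826 of the filtered
   image) so noise-only tissue yields zero detections rather than
   histogram-splitting artefacts. The microglia model uses 13 features;
   the astrocyte model uses 7 (area, mean intensity, junctions, branch
   ends, slab pixels, triple points, perimeter), with S100B needed only
   when soma features are requested.

2. **Normalisation and projection.** Feature z-scores use the mean and
   unbiased (n−1) sd of the *control* windows only; principal components
   are fitted on control z-scores and retained until ≥ 99% of variance is
   explained (minimal count, weak inequality). Loadings signs are fixed
   (largest-magnitude entry positive) for determinism. Test windows are
   transformed with control statistics only — adding test rows never
   changes another row's transform.

3. **Outlier detection.** A one-class ν-SVM (RBF kernel) is trained on
   control PC scores; rows are sorted by (section, y, x) before fitting
   so results are order-independent. A test window is an outlier when its
   decision value is negative (ties count as inliers). Because outliers
   can be hypo-intense (off-tissue, damage), outliers whose raw
   mean-intensity z-score is ≤ −1 are demoted; the filter only ever
   demotes.

4. **Proximal clusters.** Outlier window centres are clustered per
   section with DBSCAN; the default neighbour radius is the window
   diagonal rounded up (⌈100·√2⌉ = 142 µm), so two windows sharing a
   corner are neighbours. Core points need ≥ min_size neighbours
   (including themselves); noise windows stay distal. Cluster footprints
   are unions of member window squares (overlap counted once).

5. **Focal cores.** Per test section, the integrated-density z-scores of
   proximal windows are sorted ascending and the elbow of the curve is
   the focal threshold: the point of maximum perpendicular distance to
   the first-to-last chord, iterated with leading-point removal (down to
   3 points) and resolved by the modal elbow (ties → smaller threshold,
   the more inclusive choice). The curve is taken as (rank, z-value);
   since the rank axis dwarfs the value axis, the perpendicular magnitude
   is numerically the curve's maximal vertical bow from linearity in
   z-score units. The focal stage only runs when that magnitude strictly
   exceeds 0.5 — i.e. the section must show a super-linear intensity tail
   of at least half a z-score. We considered min-max scaling one or both
   axes instead; both make the magnitude of genuinely cored sections
   plateau around 0.3–0.5, rendering a 0.5 floor inoperable, so the
   z-unit reading is the one under which the floor does its published
   job. Windows above the threshold are re-clustered (DBSCAN, eps
   142 µm, min size 5) into focal clusters; focal ⊂ proximal always, and
   every test window carries exactly one label of {distal, proximal,
   focal}.

6. **Tuning.** A grid over (nu, gamma, min_size) is searched in two
   stages. Feasibility: k-fold cross-validation over control *sections*
   (sections, not windows — windows within a section are spatially
   correlated and window-level folds would leak; with fewer sections than
   folds this degrades to leave-one-section-out), a combination being
   feasible iff the full proximal pipeline yields zero clusters in every
   held-out control section. Selection: among feasible combinations,
   train on all control rows and maximise total proximal footprint area
   over the test sections; ties prefer larger (nu, gamma, min_size) — the
   most conservative boundary with equal yield. An empty feasible set is
   an explicit error telling the user to widen the grid.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| window side | 100 µm | averaging scale; ~2–4 microglia per window |
| overlap | 0.5 | spatial resolution of the label map (50 µm stride) |
| pixel scale | 1.5 px/µm | 20× acquisition; converts px to µm |
| Phansalkar radius / k / r | 60 px / 0.25 / 0.5 | local threshold neighbourhood and sensitivity |
| nu | tuned (grid 0.02–0.2) | upper bound on control windows outside the boundary |
| gamma | tuned (grid 0.01–5) | RBF width in PC-score space |
| eps | ⌈w√2⌉ = 142 µm | DBSCAN radius: corner-adjacent windows connect |
| min_size | tuned (grid 5–30) | smallest window count that counts as a cluster |
| intensity floor | −1 z | demotes hypo-intense outliers |
| elbow floor | 0.5 z | minimal super-linear bow to license focal search |
| variance target | 0.99 | retained PCA variance |

## The synthetic generators

The **feature-level generator** is the primary test vehicle: control
windows are per-feature Gaussians (means/sds sized for quiescent
microglia in a 100 µm window at 1.5 px/µm) plus a per-section random
effect (sd = 0.1 × feature sd, emulating section-to-section staining
variability); test sections carry a rectangular implanted activation
region (default 12×12 of 28×28 windows) with a brighter 4×4 focal core.
Inside the implant, feature means are multiplied by activation fold
changes — proximal: intensity ×1.4, area ×1.4, soma size ×1.2, branches
×0.7, branch length ×0.75, NND ×0.85; focal: intensity ×1.8, area ×2.0,
soma size ×1.4, branches ×0.55, NND ×0.65 — modulated by a per-window
latent activation intensity (sd 0.15) shared across features so that the
implant has genuine low-rank correlation structure. Cell count rises as
the inverse square of the NND fold (denser packing), circularity rises
slightly (ameboid rounding), fractal dimension falls slightly. IntDen is
derived as Mean × foreground pixel count, as in extraction.

The **image-level renderer** exercises feature extraction separately:
cells are placed by a hard-core Poisson process (minimum separation ~3
soma radii, as tiling microglia maintain exclusion zones), ramified cells
drawn as soma disks with recursive branching strokes, ameboid cells as
enlarged (×1.5), brighter (×1.8), near-branchless blobs, plus Gaussian
background noise; a paired soma-only channel mimics S100β. Keeping the
two generators decoupled isolates failures: a clustering bug cannot hide
behind an extraction bug.

What the generators do *not* emulate: optics (PSF, depth attenuation),
staining gradients within a section, overlapping/touching cells, vascular
and edge artefacts, and anatomically realistic process morphology.
Passing tests therefore demonstrate the statistical machinery recovers
known spatial structure under realistic effect sizes and noise — not
performance on real tissue, which additionally depends on acquisition
quality and on the extraction front-end's robustness to those artefacts.

## Numerical choices and degenerate inputs

- Phansalkar local statistics use a square (2r+1) window via separable
  filters; background subtraction uses a square-element grey opening.
  Both are fast, deterministic stand-ins for their radial counterparts;
  at the radii involved the footprint shape is immaterial to the
  downstream features.
- Box counting uses fixed edges {2,3,4,6,8,12,16,32,64} px (≥1.5 decades
  on a 150 px window), dropping edges larger than the window; an empty
  mask has D = 0.
- Skeleton junction pixels are merged into 8-connected clusters (one
  anatomical branch point can thin to several pixels); a cluster is a
  triple point when its largest neighbour count is exactly 3.
- Empty-soma windows get soma features of 0 (not missing) so every
  window remains classifiable; a single soma in a section takes the
  window diagonal as its NND.
- OC-SVM ties (decision value exactly 0) are inliers; SVM tolerance
  1e−4; nu = 1.0 is accepted by the config but libsvm cannot solve it
  exactly — use nu ≤ 0.99.
- DBSCAN border points follow scikit-learn's deterministic first-claim
  semantics on (section, y, x)-sorted rows.
- Elbow iteration stops with 3 points remaining (a chord needs two
  endpoints and one interior candidate); fewer than 3 proximal windows
  yield a no-elbow result that never passes the floor.
- Zero-variance features are dropped at normalisation with a warning.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full workflow at 4+4
sections × 784 windows (feature level), 20-point-set DBSCAN oracle
comparisons (n ≤ 60), 2 000-point ν-property checks over 5 seeds, and 50
rendered sections (200 µm², densities 100–600 cells/mm²) for the
automated-count validation — sizes chosen so the whole suite completes in
a few minutes on one CPU while every stage still operates in its intended
regime.

## Known limitations

- Exact numerical parity with ImageJ/MorphoLibJ operators is a non-goal;
  the soma chain is a simplified equivalent validated by count agreement.
- The elbow magnitude is measured in z units; sections with many proximal
  windows but a weak core can still pass the floor if their tail bows by
  more than 0.5 z. The floor is configurable where stricter behaviour is
  wanted.
- Inferential statistics (mixed models, post-hocs) are out of scope; the
  package emits tidy per-window and per-region tables for external
  statistical software.
- 3-D (z-resolved) morphometry is not supported; z-stacks are
  max-projected.
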