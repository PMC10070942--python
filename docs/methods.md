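# Methods

This note records the models, conventions and numerical choices behind
`morphodyn`, and what the synthetic-data experiments do and do not
demonstrate.

## Input model

The unit of input is a labeled volume: a 3D integer grid with physical voxel
spacing (dx, dy, dz) in µm, one label per cell, 0 for the exterior, one grid
per time frame (typical acquisition: 0.5 µm sections, 30 s frames). Division
timing comes from a lineage table carrying, per cell, its parent, its birth
frame, its anaphase-onset frame (from nuclear-division timing) and its
cytokinesis frame. Segmentation, nucleus detection/tracking and any image
restoration happen upstream; the karyokinesis→cytokinesis lag is taken as
already resolved in the lineage input.

## Morphometry conventions

- **Volume** is voxel count × voxel volume — exact with respect to the
  labeling, so per-frame volume conservation (Σ cells = embryonic region)
  holds identically.
- **Surface area** comes from a marching-cubes mesh of the binary cell mask,
  lightly Gaussian-smoothed beforehand (σ = 0.7 × the smallest voxel edge,
  applied isotropically in physical space). The smoothing removes the
  voxelization staircase: on digitized balls of radius ≥ 10 voxels the
  estimate is within ~1% of 4πr² (and within 3% across anisotropy patterns
  up to 1:2), keeping measured sphericity of balls ≤ 1.02. Because σ scales
  with the spacing, areas are exactly covariant under uniform rescaling of
  the voxel size. An exposed-voxel-face estimator (exact face bookkeeping,
  but ~1.5× biased on smooth surfaces) is retained as a cross-check oracle.
  Cells thinner than 4 voxels are meshed unsmoothed.
- **Sphericity** is Wadell's ψ = π^(1/3)(6V)^(2/3)/A (1 for a sphere); the
  formula is a package convention, stated here because upstream tools vary.
- **Contacts** use strict 6-connectivity: a shared voxel face between two
  labels contributes its physical face area (dy·dz for faces normal to x,
  etc.). Diagonal adjacency is deliberately excluded — it has no face area
  and would make "contact" resolution-dependent. Anisotropy is handled by
  the face areas themselves, never by resampling.
- **Integral contact area** is the plain per-frame sum in µm² (so it scales
  with frame rate; a per-minute variant is a config switch). The biphasic
  reproducibility analysis uses a 1,000 µm² threshold on this quantity.

## Normalization

Embryo size: each embryo's volume is the median over frames of the labeled
region volume; features are rescaled by f = (cohort mean / embryo
volume)^(1/3) with dimensional exponents (lengths ×f, areas ×f², volumes
×f³, sphericity untouched). Scaling features by dimensional analysis is
exact, avoids resampling artifacts, and is exactly invertible; rescaling the
images themselves is available for completeness but not the default.

Cell-cycle time: every complete cycle is resampled to 50 points spanning
25 min by natural cubic splines through the original samples (exact for
constant and linear dynamics; monotone inputs overshoot < 1%). Tracks
shorter than 4 frames cannot support a cubic spline; they are excluded and
logged. Cells that do not complete their cycle in the recording are excluded
from time-normalized analyses.

## Mitotic rounding and swelling

Registration sets t = 0 at the last frame at or before anaphase onset and
indexes backward on the acquisition grid (0.5 min for 30 s frames); values
are copied, never interpolated. Volume dynamics are additionally divided by
the value at t = 0. The event window is estimated as the offset of the
minimum of the all-cell-type averaged dynamics within the last 10 min (ties
to the earliest offset). The rise is tested per cell type by a one-sided
paired t-test between per-embryo means of the begin (−7.5 to −6.5 min) and
end (−1.0 to 0 min) windows. Window means (not single frames) are used
because the windows span 2–3 frames; the one-sided form encodes the
directional hypothesis (an increase) and makes the null rejection rate equal
α, which the calibration tests verify. Degenerate tests (all paired
differences zero) report p = 1; fewer than 3 contributing embryos marks a
result underpowered, with no significance claim. Peak offsets break ties to
the latest offset (a monotone rise peaks at t = 0 by convention).

## Division asymmetry

Daughter volume is the median across the daughter's whole cell cycle; the
ratio is larger/smaller (≥ 1). The uncertainty band reflects segmentation
error via each daughter's one-voxel boundary layer (cell voxels with a
6-neighbor outside the cell): with L the layer volume and V the median
volume, u = (L_A/V_A + L_B/V_B)/2. The mean (rather than the sum) of the two
relative layer fractions is the package's choice where the literature
formula is not printed; the sum variant is a config switch and exactly
doubles the band. A division is significantly asymmetric when ratio − 1 > u;
cohort tables compare the cohort-median ratio with the cohort-median band.
When tracks come from the analytic generator (no raster), L is estimated as
median surface area × one voxel edge.

## Variability metrics

v = (1/n) Σ_t |f_a(t) − f_b(t)| / (f_a(t) + f_b(t)) on time-normalized,
strictly positive dynamics: 0 on identity, bounded below 1, symmetric. The
scalar volume form is M_v = |V_A − V_B| / (V_A + V_B) on median cell-cycle
volumes (reported ×100 as a percentage for cross-species comparisons). The
integral RMSD between two cells sums, over features, the RMSE of the
normalized dynamics divided by the mean of the two cells' pooled values of
that feature ("pooled" rather than per-cell mean is the package's reading of
an ambiguous normalizer; the per-cell variant is a config switch). Cell-type
distinguishability tests, per ordered type pair, whether intra-type
distances are smaller than inter-type distances by a one-sided Welch test at
p < 0.05 (a permutation alternative is a config switch); results are
reported both as the per-type fraction of others distinguished and as the
share of types above a 95% fraction. Triangle-inequality violations of the
integral RMSD are counted and reported, not repaired — the score is not
guaranteed metric, and downstream embeddings (UMAP on the precomputed
matrix) are decorative, not validated.

Lineage/generation/time groupings use Welch two-sample t-tests on the score
distributions (α = 0.01 where stated); the time-resolved analysis applies
the metric's per-time summand and compares the initial and final points of
the normalized cycle. Contact dependence compares the Pearson correlation of
per-cell variability between contacting same-generation cell pairs against
mock pairs (same generation, never contacting in any embryo), sampled
count-matched with a fixed seed.

## Contact reproducibility

Reproducibility = embryos forming the contact / embryos where both cells
completed their cycles. Variable contacts (< 1) are classified
timing-variable when, in every non-contact embryo, the cells do *not*
coexist through the contact window observed in the contact-forming embryos
(relative to co-alive onset) but a shift of one cell's lifespan by ≤ 2
frames (± 1 min; configurable, bracketing the 1-frame jitter scale) would
make them — otherwise arrangement-variable. Contacts with sub-floor integral
area and single-frame duration are flagged as false-detection candidates and
reported separately, never deleted. Neighbor reproducibility first removes,
per cell and time point, contacts below 5% of the cell's surface area, then
scores |intersection| / |union| of the two embryos' neighbor sets at each of
50 normalized time points and takes the maximum over the cycle ("min-set"
denominator available by config). Contact duration is the contacting-frame
count over the shorter cell cycle of the pair, capped at 1.

## Lineage annotation

Target and reference clouds are mapped to their principal-component frames
(centered, variance-ordered, right-handed eigenbasis, axis signs fixed by
third-moment convention). The target is swept through a full revolution
about PC1 in 2° steps crossed with swings of ±4° in 2° steps about PC2 and
PC3 (the swing extent is a package default where the procedure's magnitude
is unspecified) and the four proper axis-sign flips — the PCA frame is
proper by construction, so improper flips cannot arise from rigid motion.
After each rotation the target is rescaled per axis to the reference's
positional sd, and the minimum-cost bijection under Euclidean distance
(unsquared; "distance" is taken literally) is found with the Hungarian
algorithm. The globally cheapest (reference × transform) combination names
the target; ties break to the first combination in the documented
deterministic order. Backward tracing propagates names frame by frame
through the tracking links, checking every traced division against the
lineage tree; an inconsistency restarts annotation one frame earlier (via a
caller-supplied annotation callback) until tracing succeeds. Frames after a
restarted anchor are named by forward propagation, with daughter identities
at divisions assigned by a deterministic index-order rule (they are
ambiguous forward in time).

## Synthetic embryos

The generator defines the study conditions for every cohort-scale
experiment; real embryos provide no generative model, so all choices here
are explicit fixtures:

- **Lineage program**: the stereotyped early lineage from the 2-cell to the
  ~32-cell stage with division times on the canonical schedule (AB rounds
  ~15 min apart; the P line budding off EMS, C, D, P4), daughter volume
  ratios encoding the known P-line asymmetries, division jitter sd 1 frame,
  karyokinesis→cytokinesis lag 2 frames, developmental rate factors in
  [1/1.1, 1.1] (fastest/slowest ≤ 1.21), embryo volume spread ≤ 1.42×.
- **Mitotic programs**: sphericity +12% and volume +9.6% rising linearly
  over the last 7 min before anaphase; baselines decline 3% from birth to
  onset so the pre-mitotic minimum sits at the onset. ABa/ABp carry an
  early-plateau variant saturating 4.5 min before anaphase with a 15% droop
  of the rise, so their dynamics peak minutes early. The measured
  window-to-window increase of a linear ramp is ~0.90× the programmed
  amplitude (the begin/end windows sit at the ramp's ends), which is why
  recovered means sit near 10.6%/8.7% for 12%/9.6% programs — within the
  ±2-point recovery bands the tests assert.
- **Noise model**: per-frame multiplicative Gaussian noise (sd 1%), plus a
  per-embryo, per-cell track-level offset (sd 2%) representing biological
  inter-embryo variability. The offset sd can be modulated per founder
  lineage, per generation, or along the cycle; contact coupling replaces a
  fraction ρ of each cell's offset with the mean latent of its contact
  neighborhood, so contacting cells (which share most of their
  neighborhood) correlate strongly while distant same-generation cells do
  not.
- **Geometry**: cells partition the eggshell ellipsoid (semi-axes
  23 × 15 × 15 µm by default; tests use a half-size shell) as a power
  diagram over hierarchically placed seed points — daughters displace from
  the mother along a per-division axis fixed across embryos (optionally
  wobbled), larger daughters staying central, newborns settling over 4
  frames. Per frame, the programmed volume fractions (swelling included,
  renormalized to sum to 1 — the eggshell confines total volume) are
  realized by solving the concave semi-discrete optimal-transport dual for
  the cell weights with L-BFGS; realized fractions converge to ≪ 1% relative
  error, and rendering fails loudly if any resolvable cell misses 4.5%.
  Rendered cells are convex polyhedra: the volume program is realized in the
  raster, while the sphericity program lives in the analytic ground-truth
  tracks (a polyhedral partition cannot carry a prescribed sphericity).
- **Ground truth vs observation**: each synthetic embryo carries noise-free
  programmed tracks (the recovery target) alongside the noisy observed
  tracks the analyses consume.

What passing tests show — and don't. Recovery of programmed onsets,
amplitudes, ratios, groupings and correlations demonstrates that the
analysis code measures what it claims on data whose truth is known, at
cohort sizes matching the study conditions (32 embryos for mitosis and
variability, 8–52 for asymmetry). It does not demonstrate robustness to
segmentation artifacts, membrane-shape complexity (real cells are not
convex), apoptosis, or gastrulation-stage cell movements, none of which the
generator emulates.

## Problem sizes and determinism

Cohort-scale tests run on analytic tracks (32 embryos × ~45 cells), with
voxel rendering exercised on half-size eggshells and single frames — the
package's chosen desk-scale study conditions. Null calibrations use 1000
(paired-t) and 600 (Welch) reduced-size replicates. All randomness flows
from explicit master seeds through spawned child seeds; cohorts are bitwise
reproducible, and per-cell constants (baseline sphericity, division axes)
derive from stable name hashes so they agree across embryos and runs.

## Known limitations

- The 11-feature panel of the full analysis is configurable but defaults to
  volume, surface area and sphericity (plus optional shape extras); no
  claim is made that this matches any particular published panel.
- The integral-RMSD score is not a metric; embeddings built on it are
  qualitative.
- `detect_timing_variability` reasons about lifespans and contact windows,
  not geometry; a contact lost to simultaneous timing *and* arrangement
  changes is attributed to timing.
- The power-diagram renderer produces convex cells with exact volume
  control but makes no biomechanical claims (no cortical tension, no
  adhesion energies).
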