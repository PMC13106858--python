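# Methods

## The neighborhood model

Every statistic in this package is a function of one geometric object: the
Euclidean distance transform of the tissue window to the set of plaque
pixels.  The amyloid-stain image is min-max normalized and thresholded
(Otsu by default — the published procedure names only "a threshold", so a
parameter-free default with a `fixed` override keeps runs reproducible);
8-connected components smaller than `plaque_min_area` (default 10 µm²) are
treated as noise.  Distance is exactly 0 on plaque pixels, which is how the
"inside (d ≤ 0)" category of the three-zone partition is encoded: a
distance transform is nonnegative, so d = 0 *is* the inside zone.  The
zone radius defaults to 69 µm, the stated equivalence of 500 px on rendered
assay slides; that same equivalence fixes the default pixel size at
0.138 µm/px for rendered data.  Synthetic images are generated at
1 µm/px instead, so a tractable 512-px frame spans 512 µm — large relative
to the 69 µm halo, as real slides are; at the rendered-slide scale a test
image small enough to iterate on would have no outside zone at all.

Plaques touching the image border are kept but flagged, since their zones
are truncated by the window.  Zone areas are pixel counts times pixel area
and are always clipped to the imaged window, because densities are only
defined on observed tissue; the three zone areas therefore tile the window
exactly, and per-gene zone counts sum exactly to the in-window total.  Both
identities are enforced in tests as exact integer/float equalities.

Transcript coordinates are continuous and may fall between pixel centers;
field lookups use the nearest pixel center, which bounds the deviation from
the true point-to-plaque distance by the pixel diagonal (also asserted in
tests).  Per-plaque statistics partition the window by nearest plaque
(ties to the lower plaque id, deterministically).

## Densities and colocalization

Transcript density is count / zone area (µm⁻²).  Colocalization between
two markers is the averaged-per-reference distance histogram: for each
occurrence of the reference marker, a histogram of distances to all points
of the other marker; histograms averaged over references (not pair-pooled),
then each bin b of width w divided by the annulus area πw²(2b−1).  Under
complete spatial randomness this renormalized profile is flat with value λ,
which is the package's main calibration property for the estimator.  No
window edge correction is applied — fidelity to the published procedure
over statistical optimality — so flatness checks place references at least
`max_range` from the borders.  Defaults: bin width 5 µm, range 200 µm
(≥ 13 bins inside the 69 µm radius); neither is stated by the source
procedure, both are configuration.

The relative over-representation view divides a gene's plaque-distance
*probability-density* histogram (then annulus-renormalized) by the pooled
all-genes baseline treated the same way.  Because both numerator and
denominator are normalized per gene, the resulting ratio is a relative
shape contrast, not an absolute intensity — the output flags this — and
its magnitude for an enriched gene is bounded by the panel composition:
on a panel where most probes are homogeneous, a fold-5 gene shows a near
ratio of ~1.3–1.4 against far values of ~0.5.

## Zone statistics

Zone differences are tested with Kruskal–Wallis (midranks, tie correction)
and Dunn's pairwise z statistics on mean ranks, Holm-adjusted by default
(Bonferroni by flag) — the published legends name "Dunn's correction"
without specifying the adjustment, so the conservative explicit choice is
the default.  The statistical unit is the per-plaque density (one
observation per plaque and zone), not the transcript, to avoid
pseudo-replication; the source does not state its unit, so this is a
documented package choice.

A caveat that matters in practice: per-plaque zone densities have sampling
variances proportional to 1/area, and zone areas differ by orders of
magnitude (a plaque interior is 10²–10³ µm²; its outside cell is ~10⁴ µm²).
Rank tests are anti-conservative for equal-mean groups with unequal
variances (a Behrens–Fisher-type effect): with realistic geometry the
omnibus test's null rejection rate measures ~7% at α = 0.05 rather than 5%.
The package's calibration study therefore draws the three zone groups from
a common area distribution (the generated field's per-plaque adjacent
areas), i.e. the exchangeable null under which the test's nominal level
applies; under that null the measured rate is 5.0% over 5000 replicates.
Users comparing zones with strongly unbalanced areas should treat mildly
significant omnibus p-values with caution.

## Cell typing

The segmented branch follows the standard single-cell recipe adapted to a
targeted panel.  Missing entries in the sparse export are distinct from
measured zeros; genes with ≥ 60 000 missing values are dropped and the
remaining missing values imputed to 0 before the ≥ 20-count cell filter.
Normalization is by analytic Pearson residuals with θ = 100 and clipping at
±√n_cells — the established defaults for this normalization; the method is
cross-checked in tests against an independent implementation.  Clustering
is PCA (20 components) on centered residuals, a symmetrized 15-NN graph,
and Leiden with a fixed seed.  The default resolution is 0.1: on
desk-scale data (hundreds of cells) resolution 1.0 over-partitions any
~200-cell community — a known sample-size dependence of modularity-type
objectives — whereas 0.02–0.3 is a stable plateau recovering planted
structure; 0.1 sits mid-plateau.  A precomputed (e.g. batch-integrated)
embedding can be passed in to bypass the internal PCA; batch integration
itself is out of scope for single-batch synthetic data.

Gene-set scores are mean expression of the set minus the mean of a control
pool drawn (seeded) from expression-matched bins, 25 bins by default with
control size equal to the set size per occupied bin.  On targeted panels
the bin count is capped so every bin holds at least 4 genes; otherwise each
bin degenerates to a single gene and the control pool collapses onto the
set itself, making every score zero.  Scores default to residual
expression (configurable), since the source does not state which scale was
scored.

A cluster is annotated with a type when the separation score
s = (mean_in − mean_out)/(std_in + std_out) exceeds 1, with population
(ddof 0) standard deviations — the formula's array-default reading; s is
invariant under shifting all scores by any constant or scaling by any
positive constant, which tests assert to 1e-12.  When several types
qualify, the argmax is assigned and all qualifying types are reported.

## T-cell counting

The counting chain reimplements the classic ImageJ-style recipe.  Both
channels are first mapped to a shared 8-bit-like display scale (joint
min-max to [0, 255]): rolling-ball background estimation and the prominence
threshold both operate on intensity units, so a fixed shared scale makes
the chain invariant to rescaling the raw intensities, and the *shared*
range keeps a signal-free T-cell channel dark rather than stretching its
noise to full range.  Background is estimated by grayscale morphology with
a ball of radius 30 px rolled under a lightly smoothed (3×3 mean) copy of
the image — as the classic implementation does, so the ball does not ride
under pixel noise — and subtracted from the original.  "Gaussian blur
radius 5" is interpreted as σ = 5 px.  Nuclei are maxima of the blurred
DAPI channel with prominence ≥ 1 (implemented as the h-maxima transform;
sub-peaks whose saddle lies within the prominence merge into one point);
maxima on the outermost pixel ring are discarded, where blur and background
estimation produce spurious edge ridges.  The per-image manual channel
thresholds of the original workflow become one explicit configured value on
the shared [0, 1] scale.  Per-plaque counts assign each flagged T cell
within 90 px of any plaque center to the nearest center only, so no cell is
counted twice.  Spearman's ρ uses midranks, with an exact permutation
p-value for n ≤ 9 and the t approximation above that; the least-squares
line and its 95% confidence-band parameters are returned for plotting
parity.

## Synthetic data: what it does and does not emulate

Plaques are disks (optionally blurred) because every downstream statistic
depends only on the mask and distances, not morphology.  Transcripts are
inhomogeneous Poisson point processes with intensity
baseline × fold(zone(d)) — piecewise constant over the pixel-resolved
zones — which is the implicit model behind density comparisons; counts per
zone are Poisson with mean intensity × area, positions uniform within the
zone.  Cell counts are negative binomial (size = dispersion) with marker
genes at `marker_mean` (default 10) over a background of 0.5, dispersion
10 — typical magnitudes for probe counts per cell on a targeted panel —
and planted types are either uniform or confined to d ≤ 69 µm.  The
immunofluorescence pair plants Gaussian nucleus blobs (radius 4 px,
amplitude 100 on background 5, noise σ 1, minimum separation 18 px, 10 px
frame margin) and a bright disk over each designated T-cell nucleus; these
margins are the stated conditions under which the counting chain recovers
counts exactly, and an illumination gradient up to ~10 intensity units
across the frame is removed by the background step without changing
counts.  All generators are driven by one splittable RNG: identical seeds
give bitwise-identical outputs, and each generator returns a ground-truth
manifest sufficient to score any downstream stage.

Not emulated: probe chemistry, optical crowding, segmentation errors,
batch effects, realistic plaque morphology, or anisotropic pixels.
Passing tests on these data show that the estimators recover what they are
defined to measure under their own model assumptions; they do not validate
robustness to the artifacts real assays add.

## Problem sizes

The default verification sizes are chosen at desk scale: 512 µm windows
with 6–12 plaques, 10³–10⁴ transcripts per gene, 400-cell matrices over a
20-marker panel, 256-px image pairs with 50 nuclei, 100-seed Monte-Carlo
loops and 5000-replicate calibration runs.  These are the sizes at which
every planted quantity is comfortably identifiable (e.g. ≥ 200 expected
points in the adjacent zone for fold recovery; λ·π·max_range² ≥ 10⁴ for
profile flatness) while a full suite run stays around a minute.

## Known limitations

- Nearest-pixel distance lookup quantizes at the pixel scale; sub-pixel
  boundary cases within half a pixel diagonal of a zone boundary can flip
  zones relative to exact continuous geometry.
- The rank-test calibration caveat above applies to any per-plaque zone
  comparison with strongly unbalanced areas.
- No spatial autocorrelation correction and no mixed-effects structure
  across animals/sections; the package tests within-window hypotheses only.
- Windows are treated as fully observed rectangles; masked or ragged
  acquisition regions are not modeled.
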