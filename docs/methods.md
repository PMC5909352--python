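# Methods

This note documents the models, conventions and numerical choices behind
`dcemcs`, and what the synthetic phantom does and does not establish.

## Data model and conventions

A DCE series is a 4D grid `voxels[x, y, z, i]` with frame `i = 0` the
pre-contrast scan and `i = 1..T` post-contrast scans; this convention is
fixed at I/O time and never re-inferred downstream. Spacing is carried as
in-plane `dx`, `dy` (mm) and `slice_th` (mm, = dz; contiguous slices).
NIfTI-1 stores no per-frame timestamps, so scan times are reconstructed
from the header's 4th pixdim as a uniform inter-scan interval (default
60 s when the header leaves it zero). Coordinates are 0-based voxel
indices; masks are stored as unsigned 8-bit NIfTI with any nonzero value
read as foreground.

## Segmentation

The sum of intensity differences per voxel is
`SOD = Pre + Σ_{i=1..T} |Post(i) − Post(i−1)|` with `Post(0) := Pre`; the
convention makes the i = 1 term well defined and gives `SOD = Pre` for a
temporally flat voxel, so the map reduces to the pre-contrast volume in
the absence of enhancement.

Otsu thresholding uses a 256-bin histogram over `[min, max]`; the
candidate thresholds are the 255 interior bin edges and the
between-class variance `w0·w1·(μ0 − μ1)²` is computed from bin centres.
Ties — including float jitter across runs of empty bins, where the
variance is analytically constant — resolve to the lowest threshold.
Foreground means value *strictly greater* than the threshold. Otsu runs
on the whole volume, not per slice.

Mask cleanup is closing, hole filling (2D slice-wise, then 3D) and
erosion with a discrete ball of radius 2 voxels (configurable). The
closing is composed manually (dilation, then erosion with
`border_value=1`) and the final erosion also uses `border_value=1`:
tissue truncated by the field of view — the chest-wall plane and the
slice-stack faces — must not be eroded at the grid border, otherwise
lesions near the first/last slices are clipped out of the breast mask.

The suspicious-voxel conditions are (C1) max relative enhancement
`(SI − BS)/BS` above 0.3 and (C2) the post-contrast peak strictly before
the final scan; "normalised time-intensity curve" is read as relative
enhancement, and "before the end of the scan time" is strict, so a peak
at the final scan (the persistent, benign-typical pattern) fails C2.
Voxels with zero baseline are never suspicious. Candidate VOIs are
26-connected components of at least 10 voxels (configurable), largest
first. Both conditions are ratio/ordering statements, so the suspicious
mask is invariant under global intensity scaling.

## Features

* Slice area `nₖ·dx·dy` (mm²) and slice perimeter as a bare
  boundary-voxel count (4-connectivity, grid border = background); the
  printed perimeter formula carries no spacing factor, so the count is
  the default and `perimeter_mm` in the config multiplies by `dx`.
  Slice-wise values are aggregated as the median; an even count takes the
  mean of the two middle values.
* Compactness `S²/V` with surface `S = (6-connectivity boundary count)
  · v_size · slice_th` and `V = n·dx·dy·dz`. `v_size` must be a length
  for the surface formula to have units of area, and the targeted
  acquisitions have `dx = dy`, so `v_size = dx`.
* Eccentricity `√(a² − b²)/a` where `a`, `b` are the largest and smallest
  principal semi-axes of the voxel-centre cloud in physical millimetre
  coordinates, with semi-axis = 2·√(second-moment eigenvalue). The
  principal axes are 3D; collinear or planar clouds raise a degeneracy
  error. For a solid ball the discretisation keeps the value below 0.15.
* Dynamic features per voxel: basal signal, SOD, and the ordinary
  least-squares slope of relative enhancement against time over all
  post-contrast scans (1/s). The slope is invariant to a constant time
  offset and to intensity scaling; BS and SOD scale with intensity.

## Classifiers

The morphological channel is an axis-aligned binary tree grown by
information gain with candidate thresholds at midpoints between
consecutive distinct sorted values; ties break by lexicographic feature
name, then lowest threshold. Growth stops at pure nodes, at `min_leaf`
(default 2) instances, or at zero gain; the tree is unpruned by default.
Leaf probabilities use Laplace smoothing `(count + 1)/(n + 2)`. The
confidence factor 0.25 drives the optional pessimistic pruning variant
(upper binomial confidence limit on the leaf error rate; zero observed
errors use the exact inversion `1 − cf^(1/n)`). The tree and the
Gaussian naive-Bayes classifier are implemented in the package because
their probability contracts (Laplace leaves, an absolute per-class
variance floor of 1e-9) are part of the pipeline's definition; the
scikit-learn counterparts serve as independent cross-checks in the test
suite, and scikit-learn's stratified folding is used for the
cross-validation estimate.

The dynamic channel trains the naive-Bayes classifier on per-voxel
feature triples, each voxel inheriting its lesion's label (all training
voxels are used). At prediction time every VOI voxel is hard-labelled by
posterior argmax — ties to malignant, as everywhere in the package, to
favour sensitivity in a screening context — and the lesion's channel
probabilities are the vote fractions `D_m = n_m/N`, `D_b = n_b/N`.

## Fusion and α selection

The fused call is malignant when `α·D_m + (1−α)·M_m ≥ α·D_b + (1−α)·M_b`
(exact ties malignant). α is searched on the grid 0, 0.05, …, 1. For a
fixed α nothing is refit per lesion, so leave-one-out accuracy equals
plain accuracy over the α-selection lesions; α* is the midpoint of the
widest contiguous maximal-accuracy plateau (equally wide plateaus: the
higher-α one, favouring the dynamic channel). The accuracy curve is
piecewise constant with at most one breakpoint per lesion, because each
lesion's decision flips at the single α where its weighted margin
crosses zero.

α is selected on the **training** split. Because the unpruned tree is
perfect in-sample, feeding in-sample channel probabilities would flatten
the training curve and make α* arbitrary; the pipeline therefore refits
both classifiers without the held-out lesion when computing that
lesion's (D, M) for α selection. Selecting α on the test split — which
uses the test lesions to tune a parameter that is then evaluated on the
same lesions — is available behind the config flag `alpha_on_test` for
comparability, but it is not the default because it leaks test data.

## Evaluation

Metrics are percentages with malignant as the positive class, kept at
full precision and rounded half-up to one decimal only for display; zero
denominators yield a flagged not-a-value for that metric alone. The
McNemar test uses the exact two-sided binomial p-value when the
discordant total is below 25 and the continuity-corrected chi-square
`(|b−c|−1)²/(b+c)` otherwise (cutoff configurable); zero discordance
returns p = 1.

## The phantom

The generator produces one series per lesion: a half-ellipsoid "breast"
of mildly enhancing tissue (baseline 100 a.u., amplitude ≤ 0.1) against
near-zero air, with the lesion following

`SI(t) = BS0·(1 + A·(1 − e^(−k_in·t))·e^(−k_out·t))`, `SI(0) = BS0`,

plus Gaussian noise (SD 2% of baseline by default, clipped at zero).
Benign defaults: amplitude A ∈ [0.35, 0.8], k_out = 0, so the curve
rises monotonically and peaks at the final scan — above the 0.3
enhancement threshold but failing the peak-timing condition, which is
what makes the benign/malignant contrast non-trivial while background
tissue stays below threshold. Malignant defaults: A ∈ [0.8, 1.5] and
k_out set from a drawn continuous peak time in [120, 240] s (scans 2–4
of 9 at 60 s spacing) via `t* = ln(1 + k_in/k_out)/k_in`. Lesion shapes
are balls (benign, irregularity ρ ≤ 0.15) or star-shaped perturbations
of relative amplitude ρ up to 0.4 built from low-order directional
cosines on the sphere (malignant); the raster keeps its largest
26-connected component. Lesion centres are drawn at least
`radius·(1+ρ) + 3` voxels from air so every lesion voxel survives
breast-mask erosion, and the bounding box must fit the grid. All
randomness derives from one integer seed with per-lesion substreams
(seed + lesion index), so cohorts are bit-reproducible and extensible.

The `hard_cohort` preset overlaps the class distributions: benign
lesions get a mild washout (k_out ∈ [1e-4, 6e-4], a plateau-like curve
that is still segmentable), amplitude ranges overlap ([0.4, 0.9] vs
[0.6, 1.2]), shape-irregularity ranges overlap, and noise rises to 5%.
A lesion whose series yields no suspicious component is called benign by
both channels — absence of suspicious enhancement is itself the benign
call.

Problem sizes used by the test suite and the reproduction script — a
32×32×10 (default) or 32×32×12 (hard) grid, 9 post-contrast scans,
cohorts of 48 lesions over ten seeds — are the package's chosen study
conditions; they keep full end-to-end replication cheap enough to run
routinely while leaving dozens of voxels per lesion slice for the shape
features.

What the phantom does **not** model: pharmacokinetics (no Tofts model,
no arterial input function), Rician noise (the pipeline consumes
intensity ratios and differences, for which Gaussian noise is an
adequate stand-in), coil bias fields, motion, bilateral anatomy,
multifocal or touching lesions, and the texture heterogeneity of real
tissue. Passing tests therefore demonstrate correctness of the
algorithms and the advertised behaviour of the fusion rule under
controlled kinetic/shape contrasts — not clinical performance.

## Known limitations

* The morphological channel saturates quickly on small grids: with
  lesions a few voxels across, slice medians and eccentricity are
  coarse, which is visible in the phantom experiments as the weaker
  channel.
* Touching lesions form a single 26-connected VOI; no splitting is
  attempted.
* The feature catalogue is deliberately restricted to the retained sets
  (area, perimeter, compactness, eccentricity; SOD, basal signal, RE
  slope); the selection module exists to reduce larger tables but the
  pipeline computes only these.
* McNemar p-values near the exact/chi-square cutoff can differ by up to
  about 0.02 between variants; the cutoff is configurable.
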