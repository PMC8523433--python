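# Methods

## The measurement problem

Outside the foveal center, cone photoreceptors appear in high-magnification
cSLO reflectance images as small bright dots arranged in a quasi-triangular
mosaic. Quantifying that mosaic — how many cones per mm², how regularly
they pack, how far apart they sit — yields biomarkers of photoreceptor
health. The pipeline here reproduces the standard computer-assisted
workflow: eccentricity-aware ROI selection, local-maxima cone detection,
and Voronoi/Delaunay mosaic metrics, together with the agreement and
repeatability statistics used to validate such measurements.

## Coordinate conventions and ROI geometry

Images are 2-D grids with origin at the top-left pixel center, x along
columns, y along rows; physical coordinates are `pixel index × pixel
scale` (default 1.5 µm/px). Visual angle converts to retinal distance at
291 µm/deg, the conventional emmetropic-eye scale. ROI centers lie at
`deg_to_um(ecc)` from the fovea along a configurable meridian→axis map;
the right-eye default maps temporal→+x, nasal→−x, superior→−y,
inferior→+y, and a left eye mirrors x. Image chirality varies between
devices and export paths, so the map is explicit and overridable rather
than assumed. ROI crops are `round_half_up(side/scale)` pixels and never
clip silently; the crop origin is recorded so ROI-local coordinates map
back to the composite image.

The detection radius follows published cone inner-segment diameters:
2.63, 3.17, 3.55, 3.68, 3.74 µm at 2, 3, 5, 7, 9°. Between tabulated
eccentricities the radius is linearly interpolated (inner-segment diameter
grows smoothly), and clamped to the endpoints outside [2°, 9°].

## Cone detection

Preprocessing converts an ROI to a 16-bit sharpened image: min–max rescale
to [0, 65535] (an identity cast is available; the mapping used by
acquisition software is rarely documented, so ours is declared and
configurable), then convolution with the DC-preserving kernel
[−1 −1 −1; −1 12 −1; −1 −1 −1]/4 using replicate padding, rounded half-up
and clamped.

Detection is a fixed, deterministic contract:

1. **Candidates** are pixels ≥ every pixel within Euclidean distance
   `r = radius_um / pixel_scale`. Connected equal-intensity candidate runs
   (8-connectivity) collapse to their centroid. Adjacent candidates within
   distance ≤ r necessarily tie, but for r < √2 diagonal neighbors may
   differ, so components are additionally split by intensity value.
2. **Greedy suppression**: candidates ranked by intensity (ties broken by
   (row, col)) are accepted unless an accepted cone lies within r.
3. **Prominence**: a candidate needs `intensity − min(disk of radius r) ≥
   noise_threshold` (default 1.00, native intensity units). The disk
   minimum is the simplest local reference for a minimum-height-difference
   ("noise") parameter.
4. **Edge exclusion**: maxima closer than `edge_exclusion_px` to a border
   are discarded; the default band is `ceil(r)` pixels, where disk
   neighborhoods are incomplete. (A 1-pixel border is available; which
   band acquisition plugins use is typically undocumented.)

Every choice (plateau centroids, lexicographic ties, half-up rounding) is
made for bit-reproducibility: the same image and parameters always give
the same cone set. `brute_force_maxima` re-implements the identical
contract with naive per-pixel disk scans and exists purely as a test
oracle; the production path must match it exactly, coordinate for
coordinate, on randomized images.

## Mosaic metrics

* **Density** = n / (side/1000)², cones/mm², over the full ROI area.
* **Voronoi neighbor counts** come from the ridge structure of the
  tessellation (`scipy.spatial.Voronoi`); this equals Delaunay natural-
  neighbor adjacency, which the tests exploit as an independent oracle.
  Cells that are unbounded or whose vertices leave the ROI rectangle have
  censored counts; they are flagged and excluded from hexagonality.
* **Hexagonality** = percent of bounded-cell cones with 5–7 neighbors.
  With no bounded cell the metric is NaN, never 0.
* **ICD** = mean length of unique Delaunay edges; an option drops edges
  incident to convex-hull vertices, which are elongated by the window and
  otherwise bias the mean upward by a few percent on rectangular crops.
  Whether published plugin pipelines average per edge or per cone is
  undocumented; we average per unique edge, hull exclusion off by default.
* **NND** = per-cone distance to the closest other cone (kd-tree), mean
  over all retained cones, no border exclusion — matching a plain
  particle-distribution analysis.

Undefined metrics on degenerate inputs (< 2 cones for NND, < 3
non-collinear for Delaunay, < 4 for Voronoi) are NaN sentinels.

## Statistics

`bland_altman` summarizes paired differences d = a − b by mean, sd (n−1),
limits of agreement mean ± 1.96·sd, a one-sample t-test of zero mean
difference, and an OLS regression of d on (a+b)/2 for proportional bias.
The 1.96 multiplier is exact, matching the symmetric intervals reported in
practice.

`icc_2way_random_single_absolute` is ICC(2,1):
(MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n), with the 95% CI from
the F-distribution construction with Satterthwaite degrees of freedom.
Exactly identical sessions short-circuit to ICC = 1.0 so perfect agreement
is not blurred by floating-point cancellation.

`friedman_test` uses within-block mid-ranks and the classic statistic
divided by the tie correction 1 − Σ(t³−t)/(nk(k²−1)); a fully tied table
returns statistic 0, p = 1. `wilcoxon_signed_rank` drops zero differences,
uses mid-ranks of |d| and W = min(W⁺, W⁻); the p-value is exact by
convolution over sign assignments for n ≤ 20 without ties, otherwise a
normal approximation with tie-corrected variance and continuity
correction. `holm_bonferroni` reports step-down rejections and adjusted
p-values (running max of (m−i+1)·p, capped at 1) in input order. All four
are validated in the test suite against scipy, pingouin and statsmodels
implementations and against seeded null simulations (empirical type-I
error within 0.05 ± 0.02).

## Synthetic mosaics

`generate_mosaic` builds a triangular lattice at spacing
s = √(2/(√3·D)) — so target density has a closed form — jitters each site
with isotropic Gaussian noise (sd = jitter_frac·s), deletes sites
independently with probability dropout_frac, and drops points that leave
the region. `render_image` draws each cone as a Gaussian of
sd = psf_sigma_um (default 2.1 µm ≈ 5 µm FWHM, the lateral resolution of
the cSLO class being emulated) with lognormal peak amplitude
(CV = reflectivity_cv, the "inconsistently increased reflectivity" of real
cones), over a constant background, plus optional white sensor noise,
quantized to integers in a 16-bit container.

Healthy presets use the median densities 20 022 / 14 946 / 11 452 /
10 818 / 10 790 cones/mm² at 2/3/5/7/9°, with jitter 0.15, dropout 0.05,
reflectivity CV 0.2. Pathology presets (`mild`, `severe`) are sparse,
heavily jittered, high-dropout lattices whose analyzed density and NND
fall in the ranges observed over atrophic lesions.

**Amplitude and noise defaults.** The renderer uses a mean cone peak of
180 over a background of 30 — an 8-bit dynamic range inside the 16-bit
container, the way acquisition software typically stores converted data —
and `background_sd = 0`: integer quantization is then the only intensity
noise, representing multi-frame-averaged acquisitions in which residual
sensor noise sits below the quantization step. This default matters. The
detector's prominence threshold of 1.00 is calibrated to such
high-signal-to-noise averaged images; after min–max stretching to 16 bits
it filters almost nothing, so any supra-quantization white noise seeds
spurious maxima in the gaps between cones wherever the gap exceeds the
suppression radius. Raising `background_sd` to even ~2 DN reproduces that
failure mode — densities inflate by several percent at 7–9° and severalfold
in the sparse pathology regime — which mirrors the known fragility of
threshold-1.00 local-maxima counting on noisier data. The parameter is
exposed precisely so users can study that regime; the default represents
the clean averaged images the method presumes.

What the generator does *not* emulate: vessel shadows, patchy (spatially
correlated) atrophy, rod intrusions, waveguide/Stiles–Crawford directional
effects, registration artifacts. Passing tests therefore demonstrate
correctness of the measurement chain on mosaics of known geometry, not
performance on real pathology. Two concrete consequences: real images
carry residual structured background the presets omit, and the simulator's
hexagonality under heavy jitter bottoms out near the Poisson-Voronoi
plateau (~75%), above the 58–71% seen over real atrophy, where patchy cone
loss produces more irregular tessellations.

## Validation experiments (`conemosaic.experiments`)

* **Lattice closed forms** — a noise-free s = 10 µm lattice is rendered at
  0.25 µm/px (supersampled so pixel quantization of peak positions does
  not confound sub-1% geometric tolerances), detected, and measured on an
  interior window (30 µm margins, half-open bounds): density within 2% of
  11 547/mm², hexagonality 100%, hull-excluded ICD and NND within 1% of
  10 µm.
* **Preset recovery** — at each healthy preset, 10 seeds: detected vs
  ground-truth cones compared on a common interior window (9 µm margin,
  beyond the edge-exclusion band) so both densities share one footprint;
  seed-averaged density and NND agree within ±10% (typically 3–7% low at
  2°, where the PSF merges the tightest pairs, and <2% elsewhere).
  Monotone density decline across eccentricity is assessed on 480 µm
  fields, where the Monte-Carlo error of the mean is several times smaller
  than the 0.3% density gap between the 7° and 9° presets.
* **Repeatability** — 10 synthetic subjects (lognormal inter-subject
  density factors, CV 0.12, spanning a range comparable to healthy
  cohorts), each rendered twice with independent reflectivity draws from
  the same ground truth; ICC(2,1) per metric. Density and spacing ICCs
  come out > 0.9, hexagonality distinctly lower — the same ordering
  reported for real test–retest data.
* **Calibration** — 2000-replicate null simulations for Friedman and
  Wilcoxon; Holm sandwich property on random p-vectors; ICC vs an
  independently coded ANOVA; Bland–Altman exactness on identical inputs.

Problem sizes (240 µm ROIs for recovery, 480 µm fields for the decline
check, 60–200 oracle images, 2000 null replicates) were chosen so each
experiment's Monte-Carlo error is small against the tolerance it checks
while the whole suite runs in minutes on one core.

## Known limitations

* The detector reports no sub-pixel refinement beyond plateau centroids;
  at the native 1.5 µm/px scale, peak quantization adds ~0.4 µm of
  coordinate noise, visible in NND more than ICD.
* Dim cones adjacent to bright ones within the suppression radius are
  merged — a conservative undercount that grows with density and with the
  PSF/spacing ratio; it is the dominant recovery error at 2°.
* The Fiji/BioVoxxel plugin chain the pipeline emulates is not bit-exactly
  reproduced (its exact maxima semantics and edge handling are
  undocumented); this implementation fixes its own deterministic contract
  instead.
* Fovea localization, frame registration, stitching and vessel avoidance
  are upstream inputs, not package functionality.
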