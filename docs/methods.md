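# Methods

## The measurement chain

The pipeline reimplements a macro-style 3D FISH quantification as a tested
library. All grids are `(z, y, x)` with anisotropic voxels, default
(0.5, 0.0662, 0.0662) µm — the axial step is ~7.5× the lateral pitch, and
several choices below exist because of that anisotropy.

**Nuclear mask.** The DNA stain is blurred with a 2D Gaussian (σ = 10 px)
applied per z-slice. The blur is deliberately *not* 3D: a scalar σ of
10 voxels would smear ~5 µm axially and destroy the mask; the original
macro ran a scalar-σ blur on the same anisotropic stacks. Thresholding is
the iterated-intermeans ("Default"/isodata) fixed point
t = (mean ≤ t + mean > t)/2, computed on a 256-bin histogram spanning the
whole stack's min–max range ("stack histogram" semantics) and mapped back
to raw units. Components are 3D 26-connected; a floor of 10 000 voxels
(≈ 22 µm³) removes debris. Touching nuclei can optionally be split with a
distance-transform watershed (`split_touching`), off by default because the
intended fields are sparse.

**Spot detection.** Difference of Gaussians, σ₁ = 2 px minus σ₂ = 4 px,
again per slice, without scale normalization — blur difference, not
scale-space theory. Both blurs are quantized to integer grey levels before
subtracting and negatives clip to zero, reproducing 16-bit image
arithmetic. That quantization is not cosmetic: it is what keeps the DoG of
a blank field identically zero so that blank fields yield zero objects.
The binarization threshold is `min(Otsu, 250)`: on spot-rich images the
256-bin Otsu value sits far above 250 and the manual cap wins (keeping dim
true foci); the cap is also what makes blank or degenerate images behave
(see "Noise model"). Otsu ties break toward the lower split, so on
histograms with an empty gap between modes the returned threshold is the
lowest equally-optimal edge — the induced mask is identical. Objects are
26-connected components of at least 25 voxels (inclusive), the 3D
object-counter convention.

**Volumes, clusters, compartments.** Volume is voxel count × dx·dy·dz.
The cluster rule is authoritative in µm³ — at least 0.6 µm³, inclusive —
and converts through the actual geometry (274 voxels only at the default
voxel size), so other acquisitions do not silently break it. An object is
nuclear if it overlaps the nuclear mask by even one voxel. Nuclear objects
belong to the label they overlap most; cytoplasmic objects to the nucleus
with the nearest centroid within 10 µm, else they stay unassigned and are
excluded from per-cell statistics (the attribution rule for cytoplasmic
objects in multi-nucleus fields is a package choice; nothing upstream
defines it). Per-cell nuclear fraction is n_nuc/(n_nuc+n_cyt), undefined —
not zero — for cells without objects, because zero-filling would bias
medians downward. Clusters count as single objects in foci counts.
Cytoplasmic clusters are kept but flagged (`has_cytoplasmic_cluster`) as a
segmentation-error indicator rather than dropped.

**Co-localization.** The post-threshold, *pre*-size-filter masks of two
channels are ANDed; intersection components of at least 25 voxels
(inclusive — the same floor used for detection) are co-localization
objects; every source object touching one is co-localized (many-to-many
allowed). Applying the 25-voxel floor before the intersection would
double-filter, so it is applied once, to the intersection. Summaries are
split into cluster vs non-cluster fractions per channel, with 0-denominator
fractions reported as NaN.

**Statistics.** The 2×2 Fisher test is exact rational arithmetic
(probability-mass two-sided convention: sum of margin-fixed tables no more
probable than the observed), delegating to scipy only above totals of
10 000. Omnibus group comparisons (one-way ANOVA, Kruskal–Wallis) and
Bonferroni correction are delegated to scipy/statsmodels — they are
standard procedures, not part of this pipeline's contribution.

## The scene simulator

`SceneParams` defaults describe the study conditions the pipeline assumes:
a (31, 512, 512) stack (15 µm z-range, ~33.9 µm field), 1–few neuronal
nuclei (ellipsoids, rz 2.5–3.0 µm, rx,y 3.5–4.5 µm), per cell and channel
Poisson(20) nuclear and Poisson(10) cytoplasmic puncta (a strongly
nucleus-retained transcript, generating nuclear fraction 2/3), puncta
volumes uniform 0.05–0.3 µm³ with peaks 6 000–25 000 counts, and with
probability 0.75 one nuclear cluster of 0.6–5 µm³ peaking at
30 000–60 000 counts. Cytoplasm is an ellipsoidal shell 2 µm beyond the
nucleus; cytoplasmic objects keep 0.8 µm clear of the envelope (the
segmentation blur makes compartment calls unreliable closer than that, and
transcripts sit throughout the cytoplasm anyway). Distinct objects keep
0.5 µm apart beyond their radii — closer pairs are not resolvable by a
0.5 µm z-step and a 2–4 px band-pass, and unresolvable truth would make
recall unmeasurable. Deliberately co-localized partners share a center
exactly. Nuclei keep a 1.5 µm cushion so their blurred masks never merge.

**Rendering and volume calibration.** Objects are solid spheres of their
nominal volume blurred by an anisotropic Gaussian PSF, peak-scaled into
their class intensity range. A naive blurred solid measures 2–4× its
nominal volume under the detection chain (an absolute threshold of 250 on
peaks of thousands keeps most of the blur halo), so the pre-blur solid is
rescaled — by bisection against the actual band-pass + threshold
measurement on an isolated patch, cached as a lookup table over
(volume, peak) — such that the noiseless measured volume equals the
nominal one. The ground-truth volume is thereby *defined* as what an ideal
noiseless measurement of the scene yields. Below an optical floor (the
band-passed footprint of a point source at the object's peak) no rescaling
can help; with the default PSF that floor sits near the smallest generated
puncta, and sub-floor objects measure at the floor.

**PSF.** Default σ = (0.4, 1.5, 1.5) voxels (z, y, x). Lateral 1.5 px
≈ 0.1 µm. The axial value is chosen so that inter-plane leakage of
in-range peaks stays below the detection threshold: at σz ≈ 0.6 voxels,
≥ 25% of peak leaks into neighbouring planes, forcing a three-plane
z-support on every object and an artificial volume floor of ~0.15–0.3 µm³.
This makes the rendered z-extent optimistic relative to a real ~0.7 µm
axial PSF — a real acquisition at this z-step cannot measure the smallest
puncta volumes accurately, and the simulator chooses volume fidelity over
axial-blur fidelity. Tests passing on these scenes therefore certify the
measurement logic, not axial-resolution claims about real data.

**Noise model.** Constant camera offset (200 counts), Poisson shot noise
on signal voxels (gain 5 counts/photon — sd ≈ 170–550 over the object
intensity range), and optional Gaussian read noise, default 0. The zero
default is deliberate: read noise below one grey level is erased by the
blur quantization anyway, while read noise of several grey levels makes
auto-thresholding of a truly blank field meaningless — Otsu lands inside
the noise floor and the quantized blur difference develops contour-band
speckle that percolates into ≥ 25-voxel components. Real blank-field
acquisitions behave because their background structure pushes the
auto-threshold far above the noise (which is exactly why the 250 manual
cap exists); the simulator gets the same contract by keeping blank fields
quantization-clean. Scenes with objects are insensitive to this choice —
shot noise dominates. Saturation QC (fraction of 65535 voxels, warn at
0.01%) is computed per channel.

**Randomness.** Everything derives from one integer seed through named
substreams: nucleus placement, one stream per cell, one noise stream per
channel. Adding a cell never perturbs earlier cells' draws; identical
(params, seed) reproduce byte-identical stacks and tables.

**What the simulator does not model.** Optical aberrations, bleedthrough,
autofluorescence texture (lipofuscin), chromogenic imagery, intensity–
count correlations within cells, axial PSF at its physical width (above),
hot pixels, or densely packed tissue. Recovery results on these scenes
bound the pipeline's behaviour under its stated assumptions, not under
arbitrary real-world imagery.

## Problem sizes used by tests and the acceptance script

Unit tests run on one- to three-cell fields of (31, 256–448, 256–448)
voxels. Recovery statistics use 60 seeded five-cell fields at the full
(31, 512, 512) default shape — 300 cells, matching the "≥ 100 cells per
group, several hundred per figure" scale of the intended application —
plus three-scene co-localization control cohorts. The acceptance script
regenerates all of these from its `--seed` and recomputes every reported
number at run time.

## Known limitations

- The measured-volume floor for sub-resolution objects is physical; the
  simulator's calibration cannot (and does not try to) place measured
  volumes below it.
- Isodata/Otsu operate on 256-bin histograms of the occupied range; images
  whose dynamic range is dominated by a single outlier will bin coarsely.
- The watershed splitter for touching nuclei is basic (smoothed distance
  maxima as seeds) and is off by default.
- Crowded cells can merge two true puncta into one detected object; at the
  default densities this costs ~1% recall and occasionally promotes a
  merged pair of foci past the 0.6 µm³ cluster cut-off (~once per few
  hundred cells), which is why classification agreement is reported
  against matched ground truth rather than assumed perfect.
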