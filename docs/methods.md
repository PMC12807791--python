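# Methods

## Problem and measurement model

A random hypoechoic sphere phantom (RHSP) is a block of tissue-mimicking
material containing randomly placed solid spheres whose backscatter is far
below the background's. Scanning it and measuring how well the spheres can
be distinguished from the speckle background probes the low-contrast
detectability of the whole imaging chain. The detectability score per
sphere is the lesion signal-to-noise ratio

LSNR_i = (S_f,i − S_b,i) / σ_b,i,

evaluated in the elevational frame where the sphere's cross-section is
largest. We keep the sign (negative for hypoechoic targets) and report the
"peak LSNR" as the most negative slab mean. The per-sphere values are
binned into 25 uniform depth slabs with half-open edges [y_k, y_{k+1});
the slab mean is the curve value and ε_k = σ_LSNR,k/√N_k its standard
error (sample SD, n−1, across the N_k spheres of the slab; slabs with
N_k ≤ 1 carry no ε, slabs with N_k = 0 no point at all).

All intensity statistics are computed on the *raw* cropped volume x0.
Denoising or bias correction would alter exactly the noise statistics the
metric is supposed to measure; the preprocessed volume x1 exists only to
make segmentation reliable.

## Pipeline stages and the parameters that matter

**Volume extraction.** Frames are stacked (depth row, lateral column,
elevational frame); depth increases away from the transducer. The scanner
overlay is removed by scanning outward from 50 px off the frame centre for
the first row/column that equals the overlay value (default 0) across all
frames; the first and last 10 depth rows are discarded (surface
reflections, weak deep signal). `depth_offset` keeps every retained row's
physical depth recoverable. Stored pixel values are used as-is; no
windowing or LUT is applied.

The elevational axis has *no physical spacing*: freehand sweep speed is
unknown and non-uniform, so every elevational operation works in frame
units and no step of the analysis converts frames to millimetres (the
simulator's ground truth does, for validation only).

**Preprocessing.** 3D non-local means with a 9-px search window and 3-px
patch (full widths), strength σ = σ₀/8 where σ₀ is the SD of the whole
volume — tying the strength to the global spread makes the denoiser
invariant to gain rescaling. Then N4 bias-field correction with an
8×4×4 B-spline control grid (depth × lateral × elevational): depth gets
the dense grid because attenuation makes it the dominant inhomogeneity
axis. We run a single fitting level at that grid (≤50 iterations,
convergence 1e-3) — stacking shrink levels would not end at the intended
grid — and estimate the field on a 2× shrunk volume for speed, resampling
the log-field to full resolution. Zero voxels are shifted by
ε = 1e-3 × mean before the log-domain fit; the output is rescaled to the
input's global mean. A strictly constant volume is returned unchanged
(its bias field is constant by definition, and N4's histogram sharpening
is degenerate there).

**Depth-adaptive thresholding.** The volume is split into 10 depth slabs.
Within a slab the intensity distribution is a two-Gaussian mixture, but at
a 20% sphere fraction the naive mean/SD are badly contaminated (the mean
shifts ~8% and the SD nearly doubles in a representative mixture), so the
background Gaussian is recovered non-parametrically: μ_k is the centre of
the tallest 256-bin histogram bin (ties toward the lowest intensity, the
conservative choice), and σ_k is the population SD of the upper
half-distribution mirrored around μ_k — S′ = {x ≥ μ_k} ∪ {2μ_k − x},
whose mean is exactly μ_k. The threshold is T_k = μ_k − 2σ_k; strictly
sub-threshold voxels form m0 (≈2.3% of pure background passes, the normal
tail). Three iterations of binary opening with the in-plane 4-connected
cross give m1. The opening is deliberately two-dimensional: a 3-iteration
3D opening would erode 3 *frames* from each elevational side, and at
freehand interframe distances (2–7 px equivalents) a 2 mm sphere spans few
enough frames that a 3D opening deletes it outright — besides treating
frame units as physically comparable to pixels, which the coordinate
model above forbids.

**Sphere separation.** The distance map is a stack of per-frame 2D
Euclidean distance transforms. A volumetric EDT with frames treated as
pixels saturates at the mask's elevational half-extent (2–3 voxels) and
develops large equal-valued plateaus spanning several spheres, destroying
the neck valleys between touching spheres; the per-frame transform keeps
the in-plane geometry, and a sphere's map peaks at its equatorial frame
centre. Watershed seeds are the 26-neighbourhood local maxima of that map
(a connected equal-valued plateau counts once, at its centroid), greedily
suppressed, strongest first, to a pairwise separation of ≥5 voxels. The
watershed floods the negated distance map restricted to m1 with
6-connectivity, so foreground support is preserved exactly. Labels whose
maximum cross-section area falls outside [0.5, 1.25]·πd²/4 are rejected
(fragments from over-splitting, clumps from under-splitting); labels
touching the first or last frame are excluded by default
(`exclude_edge_spheres`), since their true maximum cross-section may lie
outside the sweep.

**LSNR measurement.** S_f: mean of x0 over the label's max-cross-section
mask eroded 3× in-plane (rim partial-volume pixels excluded; spheres whose
mask empties are dropped with a logged reason). S_b, σ_b: mean and
population SD of x0 inside a cylinder of diameter 4d around the sphere
axis spanning *all* frames (the background is uniform at fixed depth, and
pooling frames shrinks the estimator variance), minus m0 dilated by one
voxel — the raw m0 rather than the opened m1, to exclude as many sphere
voxels as possible. Spheres with fewer than 100 background voxels or zero
σ_b are dropped. Population SD is used for σ_b (thousands of voxels);
sample SD everywhere small-n statistics appear (slab ε, RSDs).

**Repeatability.** For repeated acquisitions on identical depth settings,
the per-slab RSD is the sample SD across acquisitions over the |mean|
(×100%); the overall RSD averages slabs where every acquisition has a
value. Sphere-count RSDs are computed identically. A single-depth report
(e.g. at 2.2 cm) reads the slab containing that depth. Curves are aligned
by slab index; no depth registration is attempted.

## The simulator: what it emulates, and what it does not

The generator reproduces the *image-domain* statistics the pipeline
consumes, not RF physics. Defaults are the phantom and acquisition
conditions described above: d = 2 mm spheres at a 20% volume fraction
(≈48/mL), −40 dB backscatter contrast, 0.5 dB cm⁻¹ MHz⁻¹ attenuation at
15 MHz, 0.14×0.14 mm² pixels, 62-frame loops of 4.13 s. Each frame is
built as: partial-volume-weighted amplitude map (sphere amplitude ratio
10^(−40/20) = 0.01 within a 1 mm slice thickness), two-way attenuation
10^(−2·α·f·depth/20), multiplicative Rayleigh speckle blurred by an
anisotropic in-plane PSF, additive constant-SD electronic noise (so deep
SNR falls), and log compression to 8 bits over a 63 dB displayed dynamic
range. Frame positions are uniform steps perturbed by a fractional
`speed_jitter` and renormalized to the requested coverage — the freehand
mechanism that makes reconstructed spheres elevationally asymmetric and
displaces the mass centroid from the maximum cross-section.

Sphere centres are dart-thrown uniformly with a minimum separation of one
diameter: the physical phantom contains *solid* spheres, which can touch
(producing the connected masks the watershed must split) but cannot
interpenetrate. Setting `min_separation_mm=0` reproduces an idealized
overlapping-sphere medium; we do not use it as the default because
interpenetrating pairs closer than ~0.7 mm in-plane are unsplittable under
the 5-voxel seed rule and correspond to no physical phantom.

Chosen constants not fixed by the phantom description, with rationale:
PSF σ (axial, lateral) = (0.5, 1.0) px ≈ FWHM (0.16, 0.33) mm, typical
15 MHz linear-array resolution; electronic noise SD 1e-4 of the surface
background amplitude (≈ −80 dB noise floor); slice thickness 1 mm;
TGC off by default (an exact inverse-attenuation gain curve is available
via `ImageGeometry(tgc=True)`).

Not emulated: RF-domain beam formation, harmonic imaging and spatial
compounding, curved-array geometry, scanner overlay graphics, operator
pressure variations, and the speckle texture statistics of any particular
scanner (log-compression constants are plausible, not calibrated).
Passing tests therefore validate the *analysis* under controlled
image-domain conditions; they do not certify absolute LSNR values for any
physical scanner.

## Test and validation problem sizes

Desk-scale runs use small phantom blocks so the full pipeline stays fast
while every stage is exercised: ~2 cm depth × ~1 cm width frames
(0.14 mm pixels) and 62–121 frames. Recovery tests scan 3 cm at 62 frames
(interframe ≈ d/4); the coverage-scaling check scans the same 6.2 cm-long
phantom over 6 cm and 4 cm at exactly d/4 spacing (121/81 frames, 10
realizations). At these sizes ~200–600 spheres are placed per phantom,
giving a few hundred eligible detections per acquisition.

## Numerical choices and degenerate inputs

- Histogram binning: 256 uniform bins over the slab's [min, max]
  (configurable); a constant slab short-circuits to μ = value, σ = 0.
- Peak ties break toward the lowest-intensity bin; if the peak-bin centre
  exceeds every voxel (possible with sparse top bins), μ falls back to the
  largest voxel below it so the mirrored set is never empty.
- Boundary voxels equal to T_k are background (strict `<`).
- Slab partition boundaries at round(k·n_rows/n_slabs) (half-away-from-zero
  rounding), covering every row exactly once.
- Watershed label maps are relabelled to contiguous 1..L; components that
  end up without a seed (only possible in pathological masks) are attached
  as their own labels rather than silently dropped.
- Max-cross-section ties break toward the lower frame index.
- The area band is inclusive on both ends.
- The analysis path contains no randomness; refitting a volume reproduces
  every output byte-for-byte. All simulator randomness derives from one
  seed per acquisition.

## Known limitations

- Spheres separated mostly elevationally by less than 5 voxel units merge
  and are counted once (area stays in band); this is the price of the
  fixed 5-pixel seed rule and grows with interframe distance — the
  mechanism behind falling detection efficiency at fast sweep speeds.
- Very coarse sweeps (interframe ≫ d/4) undersample spheres between
  frames; the maximum-cross-section area then underestimates πd²/4 and
  eligible counts drop.
- Linear-array geometry only; sector/curved probes would need
  scan-conversion before analysis.
- Multi-acquisition comparison assumes identical depth settings (slab
  grids are matched by index, not registered).
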