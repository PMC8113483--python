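# Methods

`iftomo` simulates and reconstructs raster-scanned mesoscopic fluorescence
molecular tomography (MFMT) of fluorophores embedded 0.1–2 mm deep in
scattering tissue, and converts reconstructions into tumor-burden
quantities (integrated signal, calibrated cell count, thresholded volume).
Everything runs on digital phantoms; no instrument data is required.

## Imaging model

A focused excitation spot raster-scans the surface of a homogeneous slab
(default µs = 20 mm⁻¹, µa = 0.1 mm⁻¹, g = 0.85, n = 1.37 — mammary
gland / skin scale values; excitation and emission share one property set
since their measured difference is below 5%). For each of the
`(fov/step + 1)²` scan positions a de-scanned detector array records a
7×7 grid of superpixels at 0.5 mm pitch centred on the source. Larger
source–detector (S-D) separations collect photons that travelled deeper,
which is what gives the 2D raster axial sensitivity. The zero-separation
(centre) detector is excluded from the inversion measurement vector —
reconciling 49 superpixels with the 48 detectors that enter the inverse
problem — but kept in the raw 4D data, where the thresholding pipeline
uses it as the source-signal map. On the full instrument geometry
(41×41 positions × 48 detectors) the measurement vector has 80,688
entries.

Fluorescence is treated in the Born (linear) regime: the expected signal
is

    A[(s,d), v] = G_x(r_s → r_v) · G_m(r_v → r_d) · V_voxel

with excitation and (adjoint, by reciprocity) emission Green's functions.
For a laterally homogeneous slab the Jacobian needs one transport solution
per scan position plus one per *unique* detector surface position, not one
per (source, detector) pair.

## Transport engines

*Monte-Carlo*: voxelized random walk with Henyey–Greenstein scattering,
implicit capture (weight × µa/µt deposited per interaction), Russian
roulette below weight 1e−4 (survival 0.1), and Fresnel handling at the
z = 0 surface. The default boundary is index-matched (the coverslip
flat-boundary condition); an explicit outside index enables Fresnel
reflection including total internal reflection. Photons are tracked beyond
the voxel grid so the energy ledger (absorbed + escaped + roulette-killed
= launched) is exact up to MC noise; the suite checks conservation to
0.5%. Fluence is scored per launched photon as absorbed weight /
(µa · V · N), in 1/mm², and each run records its seed; photons are split
into 10 batches to estimate per-voxel standard errors. Surface sources are
pencil beams; internal sources (z > 0) emit isotropically and exist for
reciprocity checks. Default photon budgets in the test suite are 1–2×10⁵
per source — a desk-scale CPU setting, exposed as `--photons`.

*Diffusion*: the steady-state semi-infinite Green's function with
extrapolated boundary (image source across z = −2·zb, zb = 2AD with
A = 1 for the matched boundary), D = 1/(3(µa+µs')), µeff =
√(3µa(µa+µs')) ≈ 0.964 mm⁻¹ at the default properties. A surface source
is represented as an isotropic point source buried one transport mean free
path (1/µs' ≈ 0.33 mm) deep. In Jacobian assembly the Green's function is
averaged over a 2³ sub-voxel quadrature — voxel-mean fluence is what the
MC engine scores, and at coarse voxels the centre-point value differs
noticeably near the source. An exponentially distributed line source was
evaluated and rejected: it places isotropic weight shallower than the
transport mean free path and degrades agreement with MC for
forward-peaked scattering.

The two engines agree within ~10% (median relative deviation over
Jacobian entries above 1% of the column max) on a wide-separation coarse
geometry. The diffusion approximation is known to break down within about
one transport mean free path of the source; transport-level comparisons
therefore assert agreement only at depths ≥ 1/µs'.

## Inverse problem

The reconstruction minimizes the cost function exactly as stated for this
class of instruments,

    min_x ‖Ax − b‖₂² + λ‖x‖₁,   x ≥ 0,

without a ½ on the data term — consequently x = 0 is the exact minimizer
iff λ ≥ ‖2Aᵀb‖∞, which the tests assert. Non-negativity is added because
fluorophore density is physical. The solver is monotone FISTA: spectral
step 1/L with L = 2σmax(A)² from 50 deterministic power iterations (1%
safety margin), proximal step = one-sided soft threshold, and a candidate
step that would increase the objective is rejected with a momentum
restart, making the recorded objective trace non-increasing by
construction. Defaults: tol = 1e−6 relative objective change, max 5000
iterations. For production-sized tall systems (m ≥ 2n) the iteration runs
through a cached Gram matrix AᵀA in n-space; float32 Jacobians halve the
memory bandwidth that dominates these matvecs, and all scalar coefficients
are kept as Python floats because a stray NumPy float64 scalar would
silently promote the float32 iterates (a 25× slowdown we hit and fixed).

λ is selected in two stages. (1) L-curve: solve over log-spaced candidates
(default 11, spanning 10⁻⁴–10⁻⁰·⁵ of the null threshold ‖2Aᵀb‖∞,
warm-started from large to small λ — the corner of a discretely sampled
L-curve is only resolved to one candidate spacing, hence the fairly dense
default), then take the interior point of the (log residual, log L1)
curve, both axes normalized to a unit box, with the most *convex*
three-point (Menger) curvature. Both the sign convention and the axis
normalization matter: uneven candidate spacing creates concave kinks of
large unsigned curvature, and without normalization the wider-ranged
residual axis dominates the ranking. A chord-distance corner (largest
deviation from the endpoint chord) is available as an alternative
(`method="chord"`); a curve with no convex corner falls back to the
median candidate with a warning. These per-candidate solves run at a
loose tolerance (1e−5, ≤1500 iterations) — the corner location does not
depend on last-digit convergence. (2) MI fine-tune: for each
λ = factor · λ_L-curve, solve (loosely, for ranking) and run the full MI
threshold scan; the candidate whose best threshold attains the highest
mutual information against the raw reference image wins, ties resolved
toward factor 1, and only the winner is re-solved at the requested
tolerance. The default factor grid is half-octave,
{0.25, 0.35, 0.5, 0.71, 1, 1.41, 2, 2.83, 4}: the selected λ sets the L1
shrinkage bias of the integrated signal, and octave-coarse factors
produced visible gain jumps between acquisitions of different brightness
in the longitudinal closed loop. λ is re-selected per acquisition; solver
settings stay fixed across a series.

Residual selection noise matters for quantification: on desk-scale image
sizes (a few hundred pixels) the MI estimates that drive both the λ
fine-tune and the threshold choice are noisy, leaving ~±20% scatter in
the signal-per-fluorophore gain between acquisitions. This is the same
order of scatter a hardware calibration of this kind exhibits; the
longitudinal tests size their tolerances accordingly (peak/baseline
ratio ±40%, calibration R² > 0.9). A √N-rule adaptive MI bin count was
evaluated against the fixed 64 bins and rejected: it traded a small gain
in λ stability for a large loss in threshold-count accuracy.

## Thresholding

Fixed pipeline order: (1) median noise filter — raw values strictly below
the global median over the measurement vector are zeroed (the median is
computed over the included-detector data points; the cut is applied to the
whole 4D array including the centre detector); (2) centre-detector gate —
scan positions whose centre-detector value lies in [mean − 2·SD, max] are
kept (population SD; a zero-variance image passes everything with a
warning); (3) MI threshold scan — the reconstruction is masked at each of
50 linearly spaced thresholds in (0, max], the masked volume's maximum
intensity projection is compared with the raw reference image via mutual
information (64-bin joint histogram of min-max-scaled images, log₂), and
the argmax-MI threshold wins. The reference image is the gated, filtered
centre-detector map, bilinearly resampled from the scan lattice onto
voxel-centre lateral coordinates (scan positions sit on step multiples;
voxel centres are offset by half a voxel). Whether the raw reference
should be the centre-detector image, a detector sum, or a full camera
frame is ambiguous for this class of instruments; the centre-detector
choice is the default and is config-overridable. A fixed-percentage mask
(50% of max) is provided only as a comparison baseline.

## Quantification

Histology route: a slice's cell count is extrapolated as C_sub · A1/A2
from a counted sub-area (A2, C_sub) and the full tumor mask area A1;
slices (4.5 µm) sum to a tumor total. A synthetic-histology oracle in the
tests sections a simulated nucleus cloud: homogeneous density recovers the
true count within 10%, while a 2× density contrast between sampled and
unsampled regions biases the estimate by ~1/3 — the order of the 20–30%
uncertainty inherent to the extrapolation. Calibration is ordinary least
squares of cells on integrated signal (R², RMSE reported; RMSE in the
cell-count axis scale). Tumor volume is surviving-voxel count × voxel
volume; longitudinal summaries normalize volume to the first acquisition
and carry the induction (DoX on/off) annotation through. Integrated
signal is computed after MI thresholding by default (config-overridable;
whether it should precede thresholding is ambiguous).

## Synthetic data

The phantom module rasterizes analytic inclusions onto the voxel grid
(default 0.25 × 0.25 × 0.1 mm³, depth capped at 2 mm) conserving the
analytic integral to ≤2% for shapes spanning ≥3 voxels per axis (8³
supersampling of hard edges; sub-voxel inclusions deposit their integral
as a point mass). Standard fixtures: two 50 µm beads at 750 µm depth
(resolution/localization), ~3 µL fluorescein capillaries — 0.5 mm inner
radius, length set by volume — at 1.3 mm depth with 25/2.5/0.25 µM
(100:10:1) densities (linearity), Gaussian blobs truncated at half maximum
(tumors; density is a packed-cell volume fraction, converted to cells via
a 12.5 µm nominal cell, midpoint of the 10–15 µm range). The tumor time
series grows the integrated count geometrically to `growth_fold` over the
induction phase and decays back to baseline after withdrawal, with seeded
shape jitter; each scene is rescaled so its rasterized count matches the
schedule exactly. The Intralipid tank phantom defaults to the same optical
properties as tissue — a config default, not a physical claim, since the
phantom's coefficients are not independently specified.

Measurement noise is synthetic and simple: relative Gaussian
(N(0, (level·bᵢ)²), clipped at 0, default 1%) or Poisson shot noise at a
stated photon budget. Real raw data additionally contains background
autofluorescence, detector read structure, scan jitter and tissue
heterogeneity; passing tests therefore validate the algorithmic chain
(geometry, transport, inversion, selection, thresholding, calibration
arithmetic) under the stated noise model, not instrument performance on
animals. Printed point-spread widths (~200–250 µm) and absolute in vivo
sensitivities are instrument measurements and are deliberately not
asserted.

## Problem sizes and numerical choices

Closed-loop studies are scaled for a single CPU: the linearity replica
uses a 21×21 scan (5×5 mm), 0.25×0.25×0.2 mm³ voxels (n = 4000,
m = 21,168), float32 Jacobian, tol 1e−5, ≤2000 iterations; bead
localization an 11×11 scan with full-resolution 0.1 mm axial voxels; the
blob threshold study a 13×13 scan over 3×3 mm at full 0.1 mm axial
voxels (coarser axial voxels quantize the ~80-voxel ground truth too
roughly for a meaningful voxel-count comparison), with λ selected on the
first
replicate and reused and subsequent replicates warm-started (replicates
are statistically identical acquisitions). MC oracle checks use 1–2×10⁵
photons per source. Degenerate inputs are
handled explicitly: zero-extent scan axes collapse to one position,
zero-variance gate images pass all positions with a warning, empty
threshold lists and over-regularized (all-zero) reconstructions raise.

## Known limitations

Homogeneous optical properties only (per-voxel heterogeneity is out of
scope); Born linearity (no fluorophore absorption correction); single
S-D-subset joint inversion; no depth-compensation row weighting; absolute
radiometry is out of scope (all signals relative, since phantom quantum
yields are unspecified); tumor volume depends critically on thresholding
and should be read as relative across a series, not absolute.
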