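# Methods

This note documents the models, numerical choices and limitations behind
`cardiopiv`, in the order the pipeline runs them. Units: lengths in μm,
time in s, velocity in μm/s, pressure in Pa, viscosity in Pa·s, strain in
percent.

## Coordinate and unit conventions

Images are row-major with the origin top-left; `x` increases along columns,
`y` down rows; pixel indices are 0-based. Vector-grid nodes sit at
interrogation-window centers. Magnification presets map 40x → 0.25 μm/px
and 60x → 0.16 μm/px. Temporal spacing is `1/frame_rate` throughout (at
400 frames/s that is 2.5 ms).

## POD background removal

The stack is reshaped to a snapshot matrix and decomposed by SVD. The
smallest number of leading modes whose cumulative energy reaches the cutoff
(default 0.90, or an explicit mode count) is discarded and frames are
rebuilt from the rest. In brightfield sequences the static background
dominates the energy, so the retained modes are the moving tracer patterns.
Degenerate input (a stack with no energy) is an error; a truly static stack
simply reconstructs to numerical zero. Caveat: when tracer patterns repeat
*identically* every cycle (no out-of-plane exchange, closed pathlines) part
of the pattern energy becomes "static" in the POD sense and is discarded
with the background; real recordings, and the phantom with tracer turnover
enabled, do not have this degeneracy.

## Ensemble phase-correlation PIV

* Pass schedule: (96, 48, 50 %), (64, 32, 50 %), (64, 32, 75 %) —
  window px, resolution px, overlap. The final vector spacing is
  `resolution × (1 − overlap)` px exactly.
* Correlation: windows are mean-subtracted, Blackman-apodized, zero-padded
  to twice the window, and correlated by FFT. Planes from the same phase of
  every cycle are averaged before peak detection (ensemble correlation);
  frames are assigned to phases by nearest-frame binning of
  `round(cycle·period) + phase`, which handles fractional periods.
* Deformation: both frames are symmetrically warped by ± half the predictor
  field (bilinear interpolation) and re-correlated; iteration stops when the
  largest displacement update falls below 0.1 px, with at least 3 and at
  most 6 iterations per pass. Convergence is tracked per phase.
* Sub-pixel peak: three-point Gaussian estimator, falling back to a
  parabolic fit and then the integer peak when the log fit degenerates;
  equal peaks tie-break toward the smaller displacement.
* Validity: a node is invalid when its window core lacks tracer-fluctuation
  signal (the per-pixel temporal variance above the noise floor, Otsu-split
  and spatially smoothed, marks the flow support), when the correlation
  plane is flat, or when the accumulated displacement exceeds a quarter of
  the window (the standard quarter rule). Invalid vectors are zeroed and
  masked, never NaN.
* Outlier validation between passes: universal normalized-median test on a
  3×3 neighborhood with threshold 2 and a 0.1 px fluctuation floor; outliers
  are replaced by the neighborhood median and recorded. A 3×3 vector median
  filter is applied on the final pass only.
* Cycle period for binning: taken from the recording configuration when the
  cycle length is known (the usual case for a protocolized recording, e.g.
  199 pairs per cycle); otherwise estimated from the spectral peak of the
  canal velocity waveform and refined by phase-folding a patch of
  single-window waveforms over candidate periods. With few cycles the
  spectral estimate alone is uncertain by about a frame, which phase
  binning is sensitive to; the reported HR is always the spectral
  (measured) estimate.

## Differential operators

Gradients use Richardson extrapolation of second-order central differences
at steps h and 2h (fourth order on interior nodes; one-sided second order on
edges; plain central differences with a warning below 5 nodes per axis).
Invalid nodes are excluded from stencils by nearest-valid substitution.
Laplacians are formed by repeated differentiation. On a 64-node sine test
the interior error is ~50× below the second-order central difference.

## Mass-conserving reconstruction

Planar measurement implies the 2D continuity equation; the reconstruction
fits a stream function ψ on the region plus a 3-node margin with donor-ring
velocity equations (u = Dψ/Dy, v = −Dψ/Dx, central differences) and a
discrete biharmonic penalty (∇⁴ψ ≈ 0, which admits the cubic ψ of a
developed channel profile and the quadratic ψ of solid-body rotation).
Because `u` and `v` derive from one ψ through commuting difference
operators, the central-difference divergence of the reconstructed interior
vanishes to machine precision. The least-squares system is solved by a
sparse normal-equation factorization with a 1e-9 ridge.

In the full pipeline the AVC is treated with a parametric variant of the
same principle, because the general patch solver needs donors that carry the
true flux and wall positions, neither of which survives window smoothing at
a canal one to two windows wide: the canal aperture is estimated as
√2 × FWHM of the measured through-flow profile at the canal waist (the FWHM
of a parabolic jet is far less distorted by smoothing than its tails), the
per-phase flux as the column-integrated through-flow there (window smoothing
redistributes but approximately conserves flux), and the canal columns are
rebuilt with the low-Reynolds parabolic profile of that aperture and flux.
Conical 45°-divergence entrance segments, half a final window long, carry
the profile into the chamber mouths and reproduce the entrance pressure
excess of a sudden contraction.

## Hematocrit and viscosity

`N_rbc` comes from the time-averaged spatial autocorrelation of the
(temporally mean-subtracted) ventricle crop: the central peak of N identical
Gaussian blobs of amplitude a and scale σ has height `N·a²·πσ²` and width
σ√2. The peak height and width are fit with an offset Gaussian (the
zero-lag pixel, which carries the sensor-noise delta, is excluded); the
blob amplitude is the median height of detected local maxima, corrected for
sub-pixel sampling attenuation and for the subtracted mean blob coverage by
a three-step fixed point. On seeded phantoms the count is accurate to a few
percent across a two-fold density range. `Ht = 100·V_rbc·N_rbc/(A·DOF)` is
exact by construction; the single-RBC volume (default 60 μm³) and depth of
focus (default 15 μm) are explicit configuration with documented defaults —
they are instrument/organism properties the image cannot supply.

Walburn–Schneck viscosity uses C1 = 0.00797, C2 = 0.0608, C3 = 0.00499,
C4 = 14.59 L/g, TPMA = 45 mg/mL (≡ 45 g/L, making C4·TPMA/Ht²
dimensionless), Ht in percent and γ in 1/s; the poise-valued result is
converted through the named constant `PA_S_PER_POISE = 0.1`. γ is the
cycle-peak wall shear rate |dV/dn| along the high-shear (canal) wall; the
pipeline uses a 95th-percentile variant of the peak so a single noisy
gradient sample cannot set the viscosity. Blood density defaults to
1025 kg/m³.

## Pressure

`∇P = −ρ(∂u/∂t + u·∇u) + μ∇²u`; the creeping-flow mode (viscous term only)
is the default on the order-of-magnitude grounds that both Re and Wo are
far below one in embryonic hearts, and the unsteady/convective terms are
available behind a flag (cyclic central difference in phase time).

Omnidirectional integration traces parallel-ray families along eight grid
orientations (axes and diagonals), accumulates second-order trapezoidal
increments along mask-connected runs, averages the per-node estimates, and
refreshes ray-origin values from the previous iterate until the residual
(largest per-node change normalized by the field range) is ≤ 1e-3 (default;
configurable) or the iteration cap is reached, in which case the result is
returned flagged non-converged. The scheme is exact for linear pressure
fields. P := 0 at a fixed reference node every phase (the chamber-outflow
side by default); ΔP across a canal is the disc-averaged upstream-minus-
downstream difference, with negative values flagged retrograde and
probe-out-of-mask phases marked missing. Non-dimensionalization divides by
HR (s⁻¹) × μ.

Two mask details matter numerically: wall-adjacent nodes carry a
sign-flipped Laplacian kink (the smeared no-slip profile bends the other
way at its foot), so the integration mask is eroded one node off the walls;
and nodes valid in fewer than 80 % of phases are excluded.

## Wall segmentation and strain

Segmentation follows the product-field recipe: |∇u|·|u| → retain values at
or above the 90th percentile → Otsu binarization → erosion + dilation with a
disk of radius 3 → hole filling → largest connected component → traced
boundary polyline. Two numerical guards make this robust on vector-grid
data: isolated gradient spikes are winsorized at the 99th percentile of the
positive product before thresholding, and Otsu runs on the median-normalized
log product (the product spans orders of magnitude between a canal jet and
a chamber wall layer; the threshold should separate signal from background,
not strong flow from weak flow). Boundary normals come from a 5-point
moving-average smoothed polyline, oriented outward.

Deformation is accumulated by midpoint (RK2) advection of grid-seeded
material points through the cyclic phase sequence, starting at the
reference phase (end of ventricle systole, detected as the phase of minimum
ventricle area); `F = I + ∇d` with Compact–Richardson gradients, and
`E = ½(FᵀF − I)`. The literal instantaneous-gradient form of F is exposed
behind a flag for comparison but does not satisfy F = I at the reference.
Validity is trimmed `valid_margin_nodes` (default 4) away from dead zones:
bilinear sampling next to a mask edge and the ±2-node gradient stencil both
leak edge bias about two nodes each. The closure error of a full-cycle
track is reported as QC (`cycle_drift_um`). The scalar wall strain is the
largest-magnitude principal value of E in percent, and the per-phase series
is the mean of the three largest boundary values; in the pipeline the
boundary samples are taken two grid nodes inside the traced flow-support
contour and away from the canal-mouth jet, because the outermost windows
straddle the wall. For the wall-strain series (not the area/EF chain) the
displacement field is smoothed with a 1-node Gaussian before
differentiation — the top-3 statistic assumes smooth wall strain and
otherwise reports the noise tail.

The ventricle area history used for the reference-phase detection and EF is
`A(t) = A_seed · ⟨det F⟩` over well-tracked interior nodes — det F is the
local area ratio — which is insensitive to wall-adjacent window bias.

## Whole-heart metrics

* HR: dominant nonzero frequency of the Hann-windowed velocity-waveform
  spectrum with parabolic peak interpolation; an optional physiological
  band (the pipeline uses 30–600 bpm) guards against broadband jitter.
* Re = ρVd/μ with V the cycle-peak through-canal speed at the atrial inlet
  and d the inlet diameter; Wo = d√(ρω/μ) with ω = 2π·HR/60.
* EF uses the cylinder model Vol = (π/4)·L·D1·D2 with D2 = D1; geometry is
  measured once from the segmented ventricle (region-moment axes) and
  scaled through the cycle by √(area ratio). The reported projected area
  follows the printed convention A = π·L·D1; note that an ellipse of those
  axes would have area π·L·D1/4 — the convention is reproduced as printed.
* EW is the trapezoidal integral of ΔP_AVC with respect to strain over the
  diastolic window (the longest contiguous run of forward through-canal
  flow), sample order by time; the path is open because ΔP is undefined
  while the canal is closed. Stage cuts: EW < 100 Pa-% linear,
  100–300 Pa-% looped, ≥ 300 Pa-% formed; the boundary values fall to the
  higher stage (the printed strict inequalities leave them undefined).

## The synthetic phantom

What it emulates: a static bright background with smooth artifacts;
Gaussian-profile RBC-like blobs (σ ≈ 1.2 px, so a 48×48 px window holds
roughly 10–15 patterns at the default seeding) advected by a prescribed
pulsatile field; sensor noise; random blob dropout (out-of-plane blinking);
slow tracer turnover (out-of-plane exchange, 5 %/frame by default) — and,
for the two-chamber heart, prescribed periodic wall motion. The default
recording conditions are 400 frames/s for 4 s, 8 cycles of 200 frames
(199 image pairs per cycle), 0.25 μm/px, with a wide flow-free surround as
in whole-embryo framing.

Geometry and kinematics: circular atrium and ventricle joined by a straight
canal. The ventricle dilates as `s_v(t) = 1 + a·sin(2πt/T)` (default
a = 0.06) and the atrium contracts in antiphase with area-matched
amplitude; chamber interiors move with the affine dilation field, so the
walls are material and the wall strain is closed-form,
`E = ((s_v(t)/s_min)² − 1)/2`. The canal carries a parabolic profile whose
flux equals dA_v/dt (2D incompressibility at the canal), blended smoothly
into the chambers. An optional strain-free solid-body swirl exists for
circular chambers but defaults to zero: its window-smeared edge would
accumulate artificial shear in measured data.

Deliberate idealizations, hence what passing tests do *not* show: the bulk
chamber dilation field is compressible in-plane (out-of-plane motion in a
real heart supplies the missing flux), so chamber-interior mass conservation
is not emulated; tissue texture, 3D light propagation and chorion optics are
absent; wall motion is a single sinusoidal harmonic; and tracer photometry
is uniform. Real hearts have irregular geometry, asymmetric waveforms and
depth-integrated imaging — the phantom validates the measurement chain, not
the biology.

Ground-truth pressure is computed at build time by solving the Stokes
pressure-Poisson problem (5-point Laplacian of ∇·(μ∇²u), Neumann boundary
data, anchored reference node, sparse direct solve) on a stride-2 pixel
grid — an oracle independent of the production integrator. Ground-truth
hematocrit follows from the seeded density with the default V_rbc and depth
of focus (≈ 33 %, a typical teleost value); viscosity from the
Walburn–Schneck model at the analytic canal wall shear.

Problem sizes: the test and acceptance phantom runs 4 cycles of 80 frames
(HR 300 bpm) with chambers of 10.5/9.5 μm radius and a 9 μm canal on a
~63 × 87 μm frame, analyzed with a (32, 16, 50 %), (24, 12, 50 %) schedule —
a scaled-down sibling of the default recording conditions chosen so the
full pipeline completes in minutes. The canal width sits at the upper end
of the anatomical range relative to the windows (about 1.5 final windows —
the same resolvability ratio as 60x imaging of the widest canals): aperture
estimates inherit an O((kernel/width)²) widening bias that enters ΔP as
1/w³, so a validation phantom must keep the canal resolvable.

## Known limitations

* Dimensional ΔP across a canal much narrower than the interrogation window
  is biased by wall-position smearing (1/w³); the parametric canal rebuild
  removes most but not all of it. Non-dimensional comparisons (ΔP/HR·μ) and
  within-instrument trends are more robust than absolute values.
* The top-3 wall-strain statistic is an extreme-value statistic; it needs
  the displacement smoothing described above on noisy fields.
* With fewer than ~6 recorded cycles the cycle period cannot be pinned to
  one frame from the data alone; supply the protocol cycle length when it
  is known.
* Absolute (gauge) pressure calibration and 3D reconstruction are out of
  scope.
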