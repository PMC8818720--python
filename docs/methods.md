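# Methods

## Problem and representation

Wall shear stress (WSS) is the tangential viscous traction exerted by
flowing blood on the vessel wall, `tau_w = mu * du/dy` (Pa), with `mu` the
dynamic viscosity and `du/dy` the wall-normal velocity gradient. Estimating
it from 4D Flow MRI is resolution-limited: classical estimators read the
near-wall velocity gradient off a 2.4 mm grid and systematically
underestimate the true value.

This package represents an aorta-like vessel wall as a structured quad grid
of 48 circumferential (U, periodic) x 93 longitudinal (V, open) nodes.
Unwrapping the grid yields 2D *flatmaps*: (48, 93, C) arrays with a validity
mask. All quantities live on this grid:

- **wall coordinate flatmap** (x, y, z per node, mm),
- **inner coordinate flatmaps**: the wall offset by a distance `d` along the
  inward unit normal,
- **velocity sheets**: the velocity field (m/s) sampled at those inner
  points (the wall itself is not sampled — no-slip makes it identically 0),
- **WSS label flatmaps** (Pa, 3 channels).

The estimator is a convolutional network over 48 x 48 patches of a
15-channel input (wall coordinates, two inner coordinate maps at `d1 < d2`,
two velocity sheets) that outputs the 3-component WSS vector per node. A
classical parabolic-fitting estimator and a hemodynamic evaluation suite
(TAWSS, OSI, MAE, relative error, Pearson, ICC(A,1), Bland-Altman, OLS)
complete the toolchain.

## Template geometry and registration

Templates are built procedurally as tubes over a centerline with
per-station radii, using rotation-minimizing frames to avoid twist; the
U=0 generator line is the cut line. A coarse 12 x 24 template is linked to
the working 48 x 93 grid by two passes of midpoint subdivision (periodic in
U: n -> 2n; endpoint-interpolating in V: n -> 2n-1), expressed as explicit
row-stochastic matrices.

Registration onto a target wall point cloud uses Coherent Point Drift
(rigid, affine, Gaussian-kernel deformable with trade-off `alpha` and
kernel width `beta`, in mm): rigid -> affine -> deformable (alpha=3,
beta=15) on the coarse grid, two subdivision passes, then a second
deformable pass (alpha=3, beta=7) on the fine grid. Two numerical choices
matter:

- The GMM variance `sigma2` is carried from stage to stage. Re-initializing
  it per stage (the textbook default) flattens the posteriors of an
  already-aligned source and can drive the EM into the collapsed
  fixed point where the template contracts toward the target centroid.
- EM stops when the change in `sigma2` drops below 1e-5 (mm^2) or at the
  iteration cap (60 coarse / 15 fine by default). These caps bound the
  O(M^3) deformable solve on the 4464-node fine grid.

Registering a template directly to its own node cloud is an exact fixed
point. Through the coarse-then-subdivide path a residual of ~0.1 mm mean
remains: midpoint subdivision deflates the tube (chord-versus-arc, ~0.4 mm
at R = 10 mm) and the free tube ends have no target support beyond them, so
the fine deformable pass recovers the interior but leaves ~0.5 mm at the
two end rings. This is well below the 2.4 mm voxel size the workflow
targets.

## Synthetic flow as ground truth

No CFD solver is used; training and evaluation data come from analytic
laminar fields on straight tapered tubes, for which WSS has a closed form —
so every label is exact, and the estimator can be tested against known
values.

- **Geometry**: z-axis tubes, radius profile
  `R(z) = R0 (1 + a sin(2 pi k z / L))` with taper amplitude
  `a in [0.08, 0.18]`, `k in [0.75, 1.5]` cycles, `R0 in [8, 12]` mm,
  length 372 mm (93 stations at 4 mm). The taper gives the WSS map spatial
  structure along V; without it every ring is constant and pattern metrics
  degenerate.
- **Velocity**: per cross-section Poiseuille,
  `u_z(r, z, t) = s(t) Vmax(z) (1 - r^2/R(z)^2)`, with flow-rate-conserving
  `Vmax(z) = Vmax_peak (R0/R(z))^2`, `Vmax_peak in [0.8, 1.4]` m/s.
- **Waveform**: `s(t)` is a raised-cosine systolic pulse (300 ms) on a
  diastolic baseline of 0.25, cycle T = 800 ms. The baseline keeps diastolic
  frames informative instead of identically zero.
- **Labels**: `|WSS|(z, t) = 2 mu s(t) Vmax(z) / R(z)` (R in meters),
  directed along +z; `mu = 4e-3` Pa s, `rho = 1060` kg/m^3. For tapered
  tubes this is the quasi-1D (per-cross-section) value and is exactly the
  wall-normal gradient of the defined velocity field up to O(dR/dz) terms;
  exact-recovery tests use it as truth because sheets are sampled from the
  same defined field.
- **Frame times**: 6 frames through systole (including the true peak at
  150 ms) plus 3 diastolic frames. Diastole is constant under this
  waveform, so dense diastolic sampling adds no information.
- **Synthetic MRI**: analytic fields are voxelized at isotropic dx (2.4 or
  1.2 mm, voxel-center evaluation), optionally with Gaussian noise of SD =
  2% of venc (venc = 1.5 m/s) per component, seeded. Sheets are then read
  off the grid by trilinear interpolation, which reproduces affine fields
  exactly and converges to the analytic sheet values as dx -> 0.
- A blunt power-law profile `u_z ~ (1 - (r/R)^9)` (wall WSS
  `9 mu Vmax / R`) exercises the systematic underestimation of
  gradient-based estimators at MRI resolution.

What this generator does *not* emulate: secondary/rotational flow and
curvature-induced WSS asymmetry, turbulence, branch vessels, wall motion,
segmentation error, and MRI partial-volume/phase artifacts beyond additive
smoothed noise. Passing tests therefore demonstrate the machinery is
correct and the estimator can learn velocity-gradient physics at MRI-like
sampling — not clinical accuracy on real aortas.

## Network

U-Net-style: 3 encoder blocks (two 3x3 ReLU convolutions, batch norm at the
block end; 2x2 max-pool between blocks), 3 decoder blocks (bilinear 2x
upsampling, skip concatenation, two convolutions + batch norm), 1x1 output
convolution to 3 channels. Default filters (64, 128, 256); the reduced
configuration used in the bundled experiments is (8, 16, 32), ~32k
parameters.

Every convolution pads periodically along U and replicates edges along V.
Pooling preserves the circumferential periodicity, so the closed-tube
topology is respected at every depth; a practical consequence is that
constant inputs map to constant outputs, making sliding-window stitching
exactly stride-invariant on them.

Two fixed input normalizations are applied inside the model (the estimator
itself is unit-aware, callers are not affected):

- each patch is canonically centered by subtracting its mean wall
  coordinate (WSS depends only on relative geometry; the random-origin
  translation augmentation perturbs around this frame), and
- the nine coordinate channels are scaled from mm to decimeters so that
  coordinates and velocities (m/s, order 1) share a dynamic range. Without
  this the coordinate channels dominate early training and the velocity
  signal is lost.

The engine underneath is a small reverse-mode autodiff over numpy arrays
(conv via im2col, pooling, bilinear resize, box filters, broadcasting
arithmetic); gradients of every op are verified against central differences
in the test suite.

### Loss

`loss = l_MAE + omega * l_SSIM + lambda/(2m) * sum(w^2)` with omega = 1.5,
lambda = 1e-2, batch size m = 16. `l_MAE` is the mean absolute error of the
three WSS components over valid pixels. `l_SSIM = 1 - SSIM` between the
masked WSS magnitude images, with uniform 11 x 11 windows, K1 = 0.01,
K2 = 0.03, and L = the maximum true WSS in the patch. With unit exponents
and C3 = C2/2 the contrast and structure terms collapse to
`(2 sxy + C2)/(sx^2 + sy^2 + C2)`, which avoids square roots entirely and
makes SSIM(x, x) = 1 and the loss identities exact to the last bit. The L2
term sums squared convolution weights only.

### Augmentation

Per training patch: random sheet-pair choice (d1 < d2 from the extracted
distances {0.3, 0.5, 0.6, 0.8, 1.0, 2.0} mm), random-origin translation
(coordinates only), random 3D rotation (coordinates, velocities, and labels
rotate together), longitudinal sliding window, circumferential rolling
shift of at most 5 px (all channels and mask together), and with 50%
probability Gaussian-smoothed Gaussian velocity noise with SD drawn from
1-4% of venc.

### Training

Adam, cosine-annealed learning rate restarting every 10 epochs between
1e-4 and 1e-7 (defaults following the full-scale protocol), batch 16.
Patches are drawn with frame probabilities proportional to the frame's mean
|WSS| — pulsatile series spend most of the cycle in diastole and uniform
sampling under-trains the systolic dynamic range. Optionally a fixed pool
of augmented patches is drawn once and iterated per epoch (the
bounded-data regime used in the bundled experiments).

After training, batch-norm inference statistics are re-estimated by a
calibration sweep that accumulates exact global activation moments over
deterministic patches. The exponential running average underestimates the
between-batch variance badly at short training lengths, which made
eval-mode predictions unusable.

### Inference

48 x 48 windows slide along V with stride 15 (covering the 93 columns with
whole windows); overlapping predictions are averaged uniformly; the output
carries the input mask.

## Reduced-scale recovery experiment

The bundled end-to-end experiment (test suite and worked example) trains
the (8, 16, 32) network on 6 tapered-tube geometries (1 validation, 1 held
out), 10 epochs over a fixed pool of 1024 patches, lr_max = 1e-3 with
5-epoch cosine cycles, no rotation augmentation, and the sheet pair fixed
to (1.0, 2.0) mm — the MRI-resolution pair. At this parameter/compute scale
the network cannot calibrate its output across sheet depths (predictions
were biased low for shallow pairs and high for deep pairs, a spread
unchanged by doubling the training), so fixing the pair is the scaled-down
form of the full distance-randomized protocol. On the held-out geometry the
run recovers ring-averaged peak-systolic WSS within a few percent of
`2 mu Vmax / R`, per-frame Pearson pattern correlation above 0.98, and a
smaller error from 1.2 mm than from 2.4 mm voxelized inputs. Problem sizes
were chosen so the whole experiment runs in minutes on one CPU core.

## Metrics: conventions and edge cases

- Time integrals (TAWSS, OSI) use the trapezoidal rule over the given frame
  times spanning one cycle; no periodic wrap is assumed. OSI is masked
  where the magnitude integral vanishes. For square-wave reversal fixtures
  the sign change is placed midway between frames, which makes the
  trapezoidal vector integral agree exactly with the ideal square wave
  (OSI exactly 0.5 for a half-cycle reversal).
- Frame-level MAE, relative error (normalized by the peak reference WSS of
  the frame, in %), and Pearson correlation are computed on WSS
  *magnitudes* over jointly valid nodes; the training loss, by contrast,
  penalizes vector components. Pearson is reported as undefined for a
  spatially constant reference.
- ICC(A,1) is the single-measure two-way absolute-agreement coefficient
  from the ANOVA mean squares; Bland-Altman limits are bias +/- 1.96 SD
  (ddof = 1); regression is ordinary least squares.
- The parabolic baseline fits each velocity component as `v(d) = a d + b
  d^2` through (0, 0), (d1, v1), (d2, v2); the wall shear rate `a` is
  converted mm -> m, projected onto the tangent plane (shear stress is
  tangential by definition), and scaled by `mu`. Component-wise fitting and
  tangential projection are our documented choices. The fit is exact for
  any profile quadratic in d and linear in both `mu` and the velocities.
- Masked nodes carry zero values and are excluded from every loss and
  metric; tests verify that perturbing masked values changes nothing.
- Units: coordinates/distances mm, velocities m/s, WSS Pa; mm -> m
  conversion happens only inside gradient/WSS computations.

## Known limitations

- Straight-tube fixtures only; the curved-tube template builder exists but
  curved flow fields are not modeled (no Dean vortices), so curvature
  effects on WSS are untested.
- The full-scale configuration (64-256 filters, 100 epochs, 46k-combination
  datasets) is defined but not exercised end-to-end here; reported
  behaviors are for the reduced configuration.
- CPD is dense (O(M N) posteriors, O(M^3) deformable solve); registration
  of grids much finer than 48 x 93 would need low-rank kernels.
- The deformable CPD stage does not constrain the displacement to be
  locally injective; pathological targets could fold the grid.
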