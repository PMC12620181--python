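# Methods

`aquamap` is an in-silico, end-to-end implementation of simultaneous 3D
water-specific T1 and T2 (wT1/wT2) mapping of the abdomen: a Bloch-simulated
relaxation dictionary of a four-block mBIR-4 + Look-Locker acquisition, a
golden-step CASPR Cartesian-spiral sampling schedule, respiratory soft-gating,
a TV-regularized low-rank subspace reconstruction, two-point Dixon water-fat
separation with a graph-cut field map, and B0-specific dictionary matching.
A digital vial phantom plus forward k-space simulator stand in for the
scanner, so every stage is testable against known ground truth.

## Signal model and sequence timing

The acquisition consists of four 3-s blocks, each holding one adiabatic
mBIR-4 preparation followed by a Look-Locker train of 7 spoiled gradient-echo
shots x 60 profiles (TR 3.4 ms, flip 3 deg, two bipolar echoes at TE = 1.0 /
2.1 ms), then a recovery pause filling the block. Preparation durations are
10.9 / 25.9 / 40.9 / 55.9 ms (gaps inserted into the 10-ms active waveform
vary the T2 weighting); blocks 1-3 invert (180 deg), block 4 is a T2prep
(0 deg). Block 1 adds a 200-ms delay before the readout, so the shot
inversion times are 6..1230 ms (blocks 2-4) and 206..1430 ms (block 1).

The mBIR-4 waveform uses the canonical tanh/tan modulation (zeta = 10,
tan kappa = 10) at 13.5 uT peak and 3700 Hz frequency-modulation amplitude.
These shape parameters are free design choices (only peak amplitude, sweep
and duration are fixed constraints); with them the pulse inverts to < 1e-3
error across B1 scales 0.6-1.2 on resonance, while retaining the physical
off-resonance sensitivity (inversion efficiency falls to ~0.5 at 300 Hz)
that motivates B0-specific matching. The two gaps sit at the outer segment
boundaries, where the amplitude modulation passes through zero; the
frequency-modulation phase register accumulates continuously across the
whole pulse and holds during gaps.

The Bloch engine integrates the RF with 10-us hard-pulse steps (halving the
step changes nothing at the reported precision) and closed-form relaxation
elsewhere. One full pulse is precomputed as an affine spin map per (B0, T1,
T2); the 12-s four-block cycle then acts on the longitudinal magnetization as
a scalar affine map whose fixed point is the exact periodic steady state - no
warm-up iteration or convergence tolerance is needed. Readouts are ideally
spoiled; no T2* decay is modeled. Recorded signals (sin(alpha) x Mz at each
excitation) are therefore real; the per-echo off-resonance phase
exp(i 2 pi B0 TE) is applied by the forward simulator and removed again by
the water-fat stage.

## Dictionary, subspace

The mapping dictionary covers T1 in {105:15:1500} u {1550:50:3000} ms (124),
T2 in {9:1.5:120} ms (75) and B0 in {-200:20:200} Hz (21): 195 300 atoms x
1680 profile times. Matching uses an extended B0 axis to +-300 Hz. T2 > T1
corners are retained. The basis is the first k = 5 right singular vectors,
obtained from the eigendecomposition of the 1680 x 1680 Gram matrix
(float32 atoms, float64 Gram; identical to a full SVD at ~1e-6); k = 5
captures 99.97% of the squared-singular-value energy. Column signs are fixed
so each vector's largest entry is positive.

## Sampling, motion, soft-gating

Each shot walks outward from the k-space center along an Archimedean spiral
(one turn center-to-edge, linear radial progression - the ordering
deliberately oversamples the center) inside an elliptical ky-kz shutter,
claiming the nearest unclaimed grid point at each of 60 radial steps; the
start angle advances by the golden angle per acquired shot. The repetition
count defaults to ceil(shutter_area / (R x 60)) with R = 7.5, giving each of
the 28 contrasts ~ area/R distinct profiles (within +-10% on a 64 x 64 grid,
with > 99% union coverage).

The breathing surrogate is sin^6(pi t / period) - an asymmetric waveform
dwelling at end-expiration (the histogram mode) with short inspiration
peaks - plus optional linear drift and Gaussian jitter. The default period is
3.7 s: a typical adult rate chosen deliberately incommensurate with the 12-s
block cycle (a 4-s period phase-locks every repetition to the same
respiratory phase, which no real subject does). Four motion states come from
1-D k-medoids (Voronoi iterations with exact in-cluster median updates,
near-optimal vs exhaustive search in tests); the reference state is the
medoid of the most-populated cluster, and the Gaussian soft-gating weight has
its FWHM equal to the distance to the second-closest medoid. The effective
acceleration counts each location's accumulated weight capped at 1, per
contrast; at desk scale (1-2 repetitions) single contrasts can receive
near-zero total weight, making this mean-over-contrasts metric extremely
large - it is reported as defined, but only the reconstruction comparison is
used as an acceptance property.

## Forward simulation

Voxel signal at profile n, echo e:
`PD [ (1-FF) w_n + FF c_e f_n ] exp(i 2 pi B0 TE_e)`, with w/f the water/fat
steady-state timelines (fat simulated with its own T1/T2, default 350/50 ms,
at the voxel's water off-resonance; the chemical shift enters through the
multi-peak dephasing c_e = sum_p a_p exp(i 2 pi df_p TE_e)). Encoding is
label-wise: per coil and label one 3D FFT, gathered per profile - verified
against a brute-force DFT to 1e-5. Motion is a rigid feet-head shift of the
coil-weighted object (a linear phase on the fully sampled, 2x oversampled
readout); coils are treated as moving with the object, a standard
simulation approximation. Bipolar misalignment shifts echo 2 by a fractional
sample and is also encoded into an opposite-polarity DC calibration pair.
Complex Gaussian noise with a configurable coil covariance (default: 20%
inter-coil correlation) exercises pre-whitening.

The 9-peak fat spectra (in-vivo and peanut-oil presets, the latter with the
0.14-ppm water temperature shift) ship as an editable YAML data file with
values transcribed from published triglyceride spectroscopy models; a
single-peak preset (-3.4 ppm) supports analytic tests.

## Reconstruction

Per echo, the solver minimizes
`|| W^(1/2) (P F S x - y) ||_2^2 + lambda sum_i alpha_i TV(x_i)` over k = 5
coefficient volumes, with W = density compensation x soft-gating weight
applied as a square root inside the residual (weighted least squares; the
alternative reading - weights outside the square - is not used). The readout
axis is decoupled up front (1D IFFT, oversampling cropped) so the iteration
runs on the ky-kz problem with the readout as a batch axis; all FFTs are
centered/orthonormal, making the operator adjoint exact (tested to 1e-10).
The normal operator uses a precomputed per-location k x k temporal kernel.
ADMM splits the TV term (prox by fast gradient projection, isotropic 3D TV,
complex gradients treated as a joint vector field, reflexive boundaries),
with CG for the quadratic update and rho = 0.01 adapted by residual
balancing (factor 2 when the primal/dual ratio exceeds 10). Zero
initialization makes the result deterministic.

Numerical normalization: the problem is solved in units where the zero-filled
adjoint image has unit peak magnitude, so lambda weighs TV against an O(1)
data term and transfers across data scales. The default lambda = 0.01 was
calibrated on the synthetic study against reconstruction fidelity
(coefficient-domain NRMSE and signed wT2 bias): an order of magnitude weaker
leaves the weak coefficients unregularized, 3x stronger oversmooths (-6%
median wT2). The undersampling at R = 7.5 leaves most k-space locations with
a rank-1 temporal kernel, so the weak coefficients are regularization-
dominated; their residual noise floor dominates the coefficient NRMSE while
barely affecting the matched parameter maps.

## Water-fat separation and matching

The field map is estimated from the first coefficient image pair by discrete
optimization over a candidate grid (default 2 Hz over +-300 Hz, within one
ambiguity period of the 1.1-ms echo spacing): the per-voxel data cost is the
closed-form residual of the constrained fit s_e = (W + c_e F) e^{i phi0}
(W, F real; the smallest eigenvalue of a 2 x 2 Gram matrix - an
unconstrained complex fit would be exactly determined and blind to psi), the
pairwise cost is magnitude-weighted |psi_p - psi_q| (default 2e-4 per Hz
against scale-normalized data costs), and the labeling is optimized by
iterated alpha-expansion min-cut moves. This concrete energy is this
package's own construction with the same inputs/outputs as published
dual-echo graph-cut formulations; exactness on two-label problems is
verified against exhaustive enumeration. The field map is then demodulated
and every coefficient image decomposed by the exact 2 x 2 water/fat solve.

Matching searches, per voxel, the subdictionary at the grid B0 nearest the
field-map value (ties toward 0 Hz, out-of-range values clamped and counted),
maximizing the normalized inner product of the echo-1 water coefficients
with the compressed atoms; the optimal complex scale is the PD-like water
amplitude. Maps are masked at 10% of the 95th-percentile water intensity
(inclusive threshold). Joint two-echo matching exists behind a flag but is
not the default.

## Synthetic study and what it does (not) show

The standard study (48 x 48 x 12 at 3 mm, R = 7.5, 8 vials with on-grid
T1 300-1500 ms, T2 15-100 ms, fat fractions 0-25%, per-vial B0 within
+-60 Hz, 4 coils, 5% k-space noise with correlated coils, 10-mm breathing
with drift and jitter, 0.35-sample bipolar echo shift) chains every stage
and scores recovery against ground truth. At this scale the schedule has
1-2 repetitions, so each contrast sees only 1-2 respiratory phases - a much
harsher gating regime than a full-size scan (~17 repetitions); the gated
reconstruction nevertheless clearly outperforms the ungated one. Typical
results (seeds 0-2): median |wT1| error 3.0-3.3%, median |wT2| error
8-10% - the wT2 figure is floored by the 1.5-ms grid step, which is already
10% at the shortest-T2 vial - field-map error ~2 Hz, and echo-shift recovery
to < 0.01 samples. The B1 study simulates T1 500:50:1500 ms x T2
15:2.5:65 ms x B1 0.6:0.1:1.2 against the nominal-B1 dictionary; errors are
small at liver-like values and grow with T1 and T2.

The phantom is piecewise-constant with label-wise B0 and rigid 1-D motion;
real data add intra-voxel heterogeneity, non-rigid motion, T2*/flow effects
and imperfect coil calibration, none of which these tests probe. Passing
them shows the pipeline implements its stated model faithfully at matched
conditions, not that scanner-grade accuracy follows.

## Known limitations

- Fat Look-Locker dynamics use a single effective (T1, T2) at the water
  off-resonance; per-peak Bloch simulation is not modeled.
- The effective-acceleration metric degenerates at desk-scale repetition
  counts (see above).
- Alpha-expansion sweeps, by default, only the labels present in the argmin
  initialization (the full sweep is available via a flag).
- Parameter estimates are grid-valued; no interpolation between atoms.
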