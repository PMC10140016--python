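# Methods

`ptxbench` simulates the computational side of a parallel-transmit (pTx)
cardiac MRI feasibility study at 7.0 T (297.2 MHz) and 14.0 T (600 MHz):
given per-channel complex transmit (B1+), receive (B1-) and electric fields
on a voxelized torso, it computes optimal field superposition limits, static
and dynamic RF shims with local-SAR awareness, and SENSE parallel-imaging
noise amplification.  Full-wave electromagnetic solving is out of scope; a
surrogate field generator supplies inputs with the right structure, units and
qualitative frequency behavior, and the same interfaces accept real field
exports from an HDF5 container.

## Torso phantom and tissue model

The phantom is a layered elliptical cylinder (skin / fat / muscle) with two
ellipsoidal lungs and an ellipsoidal heart whose voxels form the 3-D region
of interest (ROI).  Axes: x anterior-posterior, y left-right, z head-feet;
voxels are isotropic (4 mm default, 8 mm in the small demo configuration)
with centers at `(i + 0.5) * voxel_size`.  Tissue conductivity, permittivity
and density are shipped as explicit constants per frequency
(`ptxbench/data/tissues.yaml`), with values representative of the published
tissue-property literature at 297.2 and 600 MHz.  Degenerate geometry (zero
semi-axes, a heart reaching outside the torso) is rejected at construction.

## Surrogate channel fields

Each array element is a finite straight dipole.  Its magnetic field follows
the Biot-Savart closed form of a current segment; its electric field the
quasi-static vector potential (E = -iwA, parallel to the dipole axis).
Propagation into tissue is modeled by a scalar factor
`exp(-d/delta) * exp(-2*pi*i*d/lambda)` along the straight-line depth `d`
from the element into the torso, with the conductive skin depth
`delta = sqrt(2/(w mu0 sigma_muscle))` and in-tissue wavelength
`lambda = c0 / (f sqrt(eps_muscle))`.  At 600 MHz fields therefore decay and
oscillate faster with depth than at 297.2 MHz — the central qualitative fact
the study conditions require — and this attenuation is exactly testable in
closed form.  Seeded perturbations (1.5 mm element-position jitter, 3%
amplitude ripple, small phase offsets) keep channels non-degenerate.

Conventions: B1+ = (Bx + iBy)/2 and B1- = conj(Bx - iBy)/2 (the co- and
counter-rotating circular components).  Each channel is normalized so the
sample-dissipated power at unit excitation weight is 75% of a 1 W accepted
reference (`per_channel_power`); sample loss can therefore never exceed the
accepted power.  What the surrogate does **not** capture: anatomical detail,
standing-wave interference structure, conservative-field contributions near
tissue boundaries, and inter-element scattering; passing tests demonstrate
correct algorithmic behavior on fields with realistic structure, not
agreement with any specific full-wave dataset.

Array layouts follow the three dipole building blocks — self-grounded
bow-tie (SGBT), bow-tie (BT) and fractionated dipole (FD) — in anterior +
posterior matrices: SGBT 5-6-5 (32 ch) and 7-9-9-7 (64 ch), BT 4x2 (16 ch)
and 5-6-5 (32 ch), FD 4x1 (8 ch) and 8x1 (16 ch).  The 14.0 T same-channel-
count (SCC) setups reuse the 7.0 T baseline (BL) element centers with halved
element sizes; double-channel-count (DCC) setups double the per-face count.

## Tuning and matching (co-simulation-lite)

Per-channel two-element L-networks: SGBT serial-L + parallel-C, BT serial-C +
parallel-C, FD parallel-L + serial-C.  Closed-form solutions are used where a
real-valued solution exists; otherwise a bounded Nelder-Mead search returns
the best-achievable reflection.  Capacitor loss uses a shipped ESR table
(interpolated log-linearly in C, linearly in f); inductor loss is R = wL/Q
(Q = 100 default).  Multiport S-matrices come from augmenting a synthetic
passive reciprocal impedance matrix (distance-decay coupling, PSD resistive
part by construction) with the per-channel ladders via ABCD matrices, then
S = (Z' - z0 I)(Z' + z0 I)^-1.  Reports floor at -100 dB.  The synthetic port
matrix is a stand-in for full-wave multiport data and is labeled as such.

## Optimal superposition (TXE / iSNR)

The per-voxel optimum of |b^H w| / sqrt(w^H Phi w) is sqrt(b^H Phi^-1 b)
(largest generalized eigenvalue of the rank-one signal form against the
power correlation matrix).  Phi partitions into sample (from the E-field
conjugate inner products, Hermitian PSD by construction), coil (diagonal,
default 15% of accepted power) and coupling (Laplacian-kernel distance
decay, PSD, default 10%) terms.  `intrinsic` uses the sample term only;
`realistic` the full sum; the performance ratio is 100 * realistic /
intrinsic, emitted both as a map and as its ROI mean (the headline number).
A ridge of 1e-9 * trace/N is applied when the condition number exceeds 1e12.
Maps are reported in uT/sqrt(kW) (iSNR in arbitrary units per sqrt(kW); no
absolute noise calibration is attempted).

## Local SAR engine

Pointwise Q-matrices `Q = sigma/(2 rho) E^H E` on tissue voxels; 10 g
averaging grows a centered cube in whole-voxel steps until it encloses at
least 10 g of tissue mass, then mass-averages the member matrices (linearity
makes the averaged quadratic form the mass-averaged SAR exactly).  Cubes must
stay inside the grid; voxels that cannot reach 10 g are excluded and counted.
No surface-conformal correction is applied — the choice is isolated behind
this one operation.

VOP compression visits matrices in descending spectral-norm order and absorbs
Q into an existing VOP `V = Q_core + eps*I` when `V - Q` is PSD, with
`eps = factor * max spectral norm`.  The factor is halved until the measured
mean overestimation is at or below the 15% target, then bisected so it lands
within 1% below the target when possible.  The estimator is the mean over
1000 seeded random complex-Gaussian excitations of the relative excess of the
VOP-predicted worst case over the true worst case,
`(max_V w^H V w - max_Q w^H Q w) / max_Q w^H Q w`.  A per-source-matrix
relative estimator was rejected: when a small matrix is absorbed by a much
larger one its per-matrix relative overestimation is unbounded, making the
mean diverge even as the factor goes to zero; the worst-case form is the
quantity the bound is actually used for.  The upper-bound property
(VOP max >= true max for every excitation) is asserted on every test run.
VOPs are used only inside optimization; reported SAR is always re-evaluated
on the uncompressed set.

SAR reporting convention: all maximum SAR10g values are referred to an
incident power of 1 W (the only convention consistent with printed W/kg
magnitudes for local coils); B1+ efficiencies are referred to 1 kW.  For
multi-sub-pulse SAR the default is the plain per-location sum of the
sub-pulse SAR distributions; a duty-weighted variant is exposed via a flag.

## Static pTx shimming

Forward power is booked per port as `P_fwd = (U^2/R) sum |w|^2` with
U = sqrt(2000 * 50) V exactly (2 kW per unit-amplitude port at 50 Ohm), so
equal drive of 64 channels books exactly 128 kW.  Efficiency maps rescale the
complex superposition to 1 kW total incident power in the field-set
normalization; these two power references are deliberately separate, as the
bookkeeping reference describes amplifier capability, not the map scale.

Objectives: maximize the ROI minimum of the scaled |B1+| (dropout avoidance),
or minimize SD/mean (CoV).  In phase-amplitude mode the min-B1 objective is
evaluated on the 1 kW-scaled map (otherwise amplitude growth would be a free
lunch), and amplitudes are capped at 1 (per-port power cap; log-amplitude
parameterization with floor exp(-3)).  The driver is a real-coded GA
(tournament selection, blend crossover, decaying Gaussian mutation; default
population 20 * N_ch capped at 400) followed by L-BFGS-B refinement of a
log-sum-exp softmin surrogate (sharpness beta = 50 per uT); reported metrics
always use the true hard minimum.  For 3 channels and small ROIs the result
matches an exhaustive 2-degree phase-grid search within 1%.

The SAR-aware variant minimizes (-min B1+, VOP-bounded max SAR10g) with an
NSGA-II-style non-dominated sorting GA (crowding-distance selection).  The
returned front is re-evaluated on the uncompressed SAR set and the selected
point maximizes min B1+ / sqrt(SAR10g).

## Dynamic pTx (kT points)

A kT pulse is n rectangular sub-pulses (tau_sub = 100 us) separated by
gradient blips (tau_blip = 140 us), so tau_total = n * 240 us (0.96 ms for
4 points, 1.92 ms for 8).  Under the small-tip-angle approximation the
complex flip angle is `A u` with entries
`i 2 pi gamma tau_sub B1+_c(r) exp(i k_p . r)`; gamma = 42.577478518 MHz/T;
off-resonance is neglected (hook present, unused).  Design: candidates on a
symmetric 5x5x5 (3x3x3 in fast configurations) k-grid spanning +-2 pi /
FOV_heart; greedy appending of the candidate minimizing the regularized
magnitude-least-squares cost `|| |Au| - FA_target ||^2 + lambda ||u||^2`
(variable exchange, warm-started), followed by a seeded random-placement
screening pool, single-candidate exchange sweeps to a swap-local optimum, and
a multi-start final solve.  Phase initializations stay near zero phase
(sigma <= ~0.3): variable exchange degrades sharply from wide random phase
profiles, an empirical property of the magnitude-LS landscape.  lambda is
specified relative to trace(A^H A)/m (default 1e-2).  Everything is
deterministic per seed.

A Bloch-rotation simulator (finite rotations per sub-pulse, blips as
instantaneous z-rotations by `(k_p - k_{p+1}) . r`) provides the independent
check; at a 10-degree target the designed pulses agree with the STA voxelwise
to well under 0.5 degrees, and the disagreement grows monotonically with
flip angle (checked at 5/10/30/60 degrees).

Flip-angle maps are rescaled to efficiency via
`B1eff+ = FA/(2 pi gamma tau_sub) * sqrt(P_In / (P_fwd k))` with
`k = (tau_total/1ms) * ((tau_sub + tau_blip)/tau_sub)` and P_fwd the pulse's
summed incident power in the field normalization, i.e. the pulse is referred
to a 1 ms / 1 kW-equivalent drive.  For a single sub-pulse of 1 ms with no
blip (k = 1) this reduces exactly to the static 1 kW scaling, which is
asserted as an invariant.

## SENSE g-factors

On the axial plane through the heart center, channel sensitivities come from
the B1- maps (tissue-masked); the noise covariance Psi defaults to identity
and accepts any Hermitian positive-definite matrix (e.g. the sample-loss
power correlation).  For 1-D Cartesian acceleration R along y (L-R) or x
(A-P) the alias set of a voxel is the R cyclically wrapped positions spaced
N/R; air-only positions are dropped.  g = sqrt([(S^H Psi^-1 S)^-1]_jj *
[S^H Psi^-1 S]_jj) >= 1; voxels with singular or extremely ill-conditioned
(cond > 1e12) normal matrices are flagged unresolvable and excluded from the
ROI mean/max with a count.  The formula is cross-checked against a
Monte-Carlo SENSE unfolding (1e4 correlated noise draws) to within 3%.

## Pipeline and problem sizes

`run_scenario` chains phantom -> fields -> superposition -> SAR -> baseline +
min-B1 + CoV shims -> multi-objective shim -> kT designs -> g-factor table,
writing CSVs with a config-hash manifest; identical scenarios reproduce all
outputs byte-for-byte.  The shipped demo scenario uses the 24^3 phantom with
the 8-channel FD baseline array, GA budgets of population 60-80 and 20-30
generations, a 3x3x3 kT candidate grid, and caps the VOP workload at a
seeded subsample of 800 averaged matrices with 300 test excitations; it
completes in about half a minute on one core.  These sizes are the package's
default study conditions for synthetic data; all algorithms accept the
full-resolution settings unchanged.

## Known limitations

* The surrogate fields share structure, not values, with full-wave exports:
  absolute efficiencies and SAR levels are not comparable to any published
  anatomical-model table, and per-channel field magnitudes are a few-fold
  lower than measured cardiac arrays (forward-power bookkeeping is
  correspondingly higher for flip-angle-matched pulses).
* 10 g averaging uses axis-aligned cubes without surface conformity.
* The GA/NSGA-II are compact reference implementations; they are adequate at
  the shipped problem sizes but make no effort at large-scale performance.
* Gradient blip feasibility (slew/amplitude) is not checked; blips are ideal
  k-space displacements.
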