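# Methods

`bivent` couples a quasi-static nonlinear finite-element model of a
dilated, failing biventricular heart to a closed-loop lumped-parameter
circulation and a continuous-flow ventricular assist pump, and computes
the mechanical and hemodynamic consequences of running the pump at
increasing rotor speed. This note records the model, its assumptions,
the numerical choices, and what the shipped synthetic configurations do
and do not represent.

## Geometry and fiber architecture

The solid is an idealized stand-in for a patient-specific biventricular
segmentation: a thick-walled LV built from two concentric truncated
ellipsoids (base plane at z = 0, apex at negative z), and an RV free
wall swept outward from the LV epicardium over a configurable
circumferential span. The part of the LV wall covered by the RV cavity
is labeled septum. Surfaces (`LV_ENDO`, `RV_ENDO`, `EPI`, `BASE`) and
the endocardial annulus ring are labeled at build time, as are the
markers used by the septal-shift metric: the basal septal midpoint and
the anterior/posterior junction points where the RV free wall meets the
LV.

Defaults place the unloaded LV cavity at 182 ml (`lv_endo_radius` 33 mm,
apex depth 80 mm, wall 8 mm) — a severely dilated ventricle — and the
unloaded RV near 120 ml. Node radii carry an analytic compensation
factor (`sqrt(dtheta/sin dtheta)` circumferentially, a frustum-sum
correction longitudinally) so the faceted cavity volume equals the
smooth ellipsoid volume at any mesh resolution; discrete cavity volumes
are therefore resolution-independent to round-off.

Meshes are trilinear hexahedra; the apex is closed with collapsed-hex
wedges whose interior quadrature points remain well defined. Every
element stores the parametric coordinates (theta, mu, transmural depth
d) of its nodes. Fibers follow the rule-based helix: the fiber direction
lies in the local circumferential–longitudinal plane at an angle varying
linearly with depth from −60° (epicardium, d = 0) to +60° (endocardium,
d = 1); sheets are wall-normal. The same rule covers the LV free wall,
septum, and RV free wall. In the septum, depth runs from the RV-facing
surface (d = 0) to the LV-facing surface (d = 1); in the RV free wall
from outer surface to RV endocardium. Septal fiber orientation is a
modeling convention (the literature does not fix which septal face
counts as "endocardium"); both the angles and the depth convention are
configurable.

Prolate spheroidal coordinates are provided as a standalone utility
(complex `arccosh` inversion, round-trip accurate to ~1e-12); the fiber
rule itself uses the mesh's parametric depth, which is the same
transmural normalization evaluated without numerical shell fitting.

## Passive and active material

Passive myocardium is the orthotropic exponential (Holzapfel–Ogden)
strain energy on the isochoric invariants I1, I4f, I4s, I8fs, with
moduli a, a_f, a_s, a_fs (kPa) and exponents b, b_f, b_s, b_fs. The
fiber/sheet I4 terms act only in extension (I4 > 1) by default
(tension-only fibers; switchable). Volume change is penalized by
psi_vol = ((J²−1)/2 − ln J)/D with D = 2/K; the default bulk modulus is
K = 1000·a. The shipped `chf_reference` parameter set is the calibrated
chronic-heart-failure myocardium (a=8.41, b=30.32, a_f=27.72, b_f=58.18,
a_s=3.85, b_s=50.44, a_fs=2.26, b_fs=12.42 kPa/-).

Active contraction is a time-varying-elastance fiber tension
Ta(t, l) = TMAX · Ca0²/(Ca0² + ECa50²(l)) · (1 − cos w(t, l))/2 with
sarcomere length l = lR·lambda_f taken from the full (not isochoric)
stretch, ECa50(l) = Ca0max/sqrt(exp(B(l−l0)) − 1) above the slack length
l0 (no tension below), a rise over [0, t0] and a relaxation of
length-dependent duration t_r = m·l + b. Constants default to the
canonical values of the time-varying-elastance literature (Ca0 = Ca0max
= 4.35 umol/l, B = 4.75 /um, l0 = 1.58 um, lR = 1.85 um, t0 = 0.17 s,
m = 1.0489 s/um, b = −1.429 s); they are configurable and should be
treated as representative rather than patient-derived. The total Cauchy
stress adds Ta along the deformed fiber and a fraction n_s = 0.25 along
the deformed sheet (cross-fiber transfer).

## Finite-element solver

Total-Lagrangian displacement formulation, trilinear hexes, 2×2×2 Gauss
quadrature for the isochoric + active stress and single-point
(selective-reduced) integration of the volumetric penalty. SRI is not
optional decoration: with full volumetric quadrature the coarse
near-incompressible hexes lock severely (a thick-sphere pressurization
test gives 9% of the closed-form Lamé displacement; with SRI, 99.5%).
The cost of SRI is that pointwise J at off-centroid quadrature points is
only weakly constrained (the isochoric energy is J-independent): the
element-mean J stays within 1e-2 of unity under end-diastolic loads, but
pointwise excursions up to ~4–5% occur. This is a known property of the
formulation at coarse resolution, not a convergence failure.

Residuals use the analytic first Piola stress; consistent tangents are
assembled from forward finite differences of that stress (9 directional
perturbations, vectorized over all quadrature points) plus an exact
analytic volumetric tangent. The linearized system, with base-plane
z-fixity eliminated and the annulus mean-translation/rotation constraint
appended as KKT rows, is factorized sparsely; the factorization is
reused as a chord across Newton iterations and time steps and refreshed
whenever the residual contraction stalls. Endocardial pressures are
follower loads on the deformed surface with their (finite-difference)
load stiffness included. Load continuation with automatic bisection
handles large steps.

Boundary conditions mirror the physiologic setup: all basal nodes fixed
longitudinally; the annulus ring's mean in-plane translation and mean
rotation tied to the fixed annulus center so the ring can dilate and
contract but not drift or spin.

The simple-shear cube experiment (uniform 3×3×3 hex cube, one face held,
the opposite face translated) measures shear stress from the reaction
force on the driven face. With traction-free lateral faces the converged
FE stress falls up to ~15–20% below the homogeneous closed form at large
shear — a real edge effect of the glued-plate configuration, verified by
refinement and by an exact patch test. The driver therefore defaults to
`lateral="affine"` (side faces follow the homogeneous motion), under
which the imposed boundary drives an exactly homogeneous state and the
FE result matches the closed form to solver tolerance; `lateral="free"`
reproduces the physical experiment.

## Circulation and pump

The circulation is a closed loop of four compliances (systemic and
pulmonary, arterial and venous) connected by two vascular resistances
and four ideal-diode valve resistances in the standard topology; the
two ventricular cavities belong to the FE model. The published
parameter table for the companion circulation was not available, so the
defaults are representative severe-heart-failure values (R_SYS = 1.65,
R_PUL = 0.17 mmHg·s/ml, C_SA = 1.0, C_SV = 50, C_PA = 2.5, C_PV = 6
ml/mmHg, valve resistances 0.04–0.06, heart period 1.0 s), chosen once
so the unsupported calibrated model lands in the reported severe-HF
regime (CO ≈ 1.7 L/min, LV EF ≈ 12%, elevated filling pressures) and
not revisited. Venous/arterial pressures initialize the compartment
volumes; unstressed volumes default to zero.

The pump draws from the LV cavity into the systemic arterial compliance
continuously. Its characteristic is a per-speed table of flow vs
pressure head dP = P_SA − P_LV on a 0..200 mmHg grid at 2 mmHg steps,
interpolated linearly and extrapolated linearly with the terminal
segment slope. The synthetic map mimics an axial pump: zero-head flow
0.65·(kRPM) L/min, shut-off head 2.0·(kRPM)² mmHg, slightly concave
decline, floored at zero; higher speed gives a uniformly higher curve.
Measured tables can be supplied as CSV (`rpm, dP_mmHg, flow_L_min`).

The circuit advances by backward Euler on the compliance volumes with
chamber pressures held at the coupling iterate (diode states and the
pump's piecewise-linear segment resolved inside a small damped Newton);
total blood volume is conserved to round-off by construction.

## FE–circulation coupling

At each time step a 2×2 Newton iteration on (P_LV, P_RV) matches the FE
cavity volumes to the circuit-predicted chamber volumes, with both
residual components required below 0.05 ml. The 2×2 Jacobian combines a
finite-difference ventricular compliance (two extra warm FE solves) with
the circuit's pressure sensitivity, and is reused across steps as a
chord, refreshed every ~20 steps or when an outer iteration struggles.
The default coupled step is 10 ms (20 ms for calibration loops); halving
the step changes the chamber-volume traces by well under 1% (verified in
the suite), which is adequate for the beat-level metrics this model
reports. Simulations start from an end-diastolic-like state (passive
inflation against the initial venous pressures) and run an integer
number of 1-s cycles; the last cycle is analyzed, and the beat-to-beat
EDV drift is reported as a periodicity diagnostic.

## Calibration

Stage 1 fits the eight passive constants to six-mode simple-shear data
by least squares in log-parameter space (positivity by construction),
with per-mode normalization so stiff modes do not dominate. The forward
model defaults to the analytic homogeneous-shear evaluation; the
27-element FE cube is available as the forward solver and agrees with
the analytic route to 2%. Synthetic datasets generated from known
parameters are recovered to machine precision noise-free; the suite
asserts 5%.

Stage 2 scales moduli by A and exponents by B so the passive LV
inflation course tracks the Klotz single-beat EDPVR anchored at
(EDV, EDP) = (254 ml, 23 mmHg), with normalized-curve constants
An = 27.78 mmHg, Bn = 2.76 and V0 = Vm(0.6 − 0.006 Pm). Because a
uniform scaling of all moduli (bulk included — `scaled()` keeps K/a
fixed) rescales the pressure axis of the passive P–V relation exactly,
the EDV-at-EDP anchor fixes A in closed form given any B; the fit
reduces to a 1-D bounded search over B minimizing the squared *relative*
pressure mismatch at matched volumes (relative error weights the
low-pressure toe, where the exponent is identified; courses are
interpolated in log-pressure to avoid chord bias on the exponential
curve). Parameter-recovery tests confirm a generating (A, B) pair is
refit to within 1%. The RV is co-inflated at 0.4× the LV
pressure so the septum carries a physiologic transmural load during the
fit. Note the idealized geometry's unloaded volume (182 ml) exceeds the
Klotz V0 (117 ml); the fitted curve therefore matches the EDPVR over
the physiologic limb rather than at the toe, and the optimal B sits low
in its bounds. The anchor constraint — inflation to 23 mmHg reaching
254 ml within 2% — is what downstream results depend on, and is
verified by an independent inflation after the fit.

The active calibration and study setup are joint: a preload factor
(scaling the four initial compartment pressures) anchors the
unsupported beat's EDV at 254 ml — this substitutes for the unavailable
total-blood-volume prescription — while TMAX is fitted so the stroke
volume matches EDV − ESV = 30 ml. Both scalars update each iterate from
one shared two-cycle simulation (diagonal secant); convergence is 1% on
EDV and 1.5% on SV, after which the detected end-systolic volume lands
within 2% of 224 ml. On the default mesh the calibrated model gives
LV EF ≈ 12% and CO ≈ 1.7–1.8 L/min.

## Output metrics

End diastole / end systole are detected from the PV trace as the samples
immediately preceding the isovolumic contraction and relaxation
segments (contiguous runs of ≥ 3 near-constant-volume samples at
rising/falling pressure); when the pump removes the isovolumic phases
the detector falls back to the volume extrema and logs it. Functional
metrics follow the clinical definitions: EF = (1 − ESV/EDV)·100, CO =
mean systemic flow, and cycle-mean pulmonary-venous / systemic-venous
pressures serve as PCWP / CVP proxies (the circuit has no capillary
node, hence "proxy"). Septal shift is the signed in-plane distance of
the deformed basal septal midpoint from the deformed junction line,
positive toward the LV centroid. Regional myofiber stress (f·sigma·f
along the deformed fiber) is volume-weighted over the elements of each
wall region at ED and ES; distributions are reported as volume-weighted
probability-density histograms (unit area by construction). The
isovolumic-contraction duration metric uses a 10 ml/s flow threshold,
above the coupling-tolerance noise floor.

## What the synthetic study shows — and does not

The shipped configuration reproduces, at desk scale, the qualitative
physiology of mechanical LV unloading: across the off → 12k RPM sweep,
LV EDV, LV filling pressure and LV free-wall ED fiber stress fall
monotonically; RV EDV and the CVP proxy rise; LV EF rises; the peak
diastolic leftward septal shift grows; the isovolumic plateau of the LV
loop disappears. These are the directional findings the model family is
built to expose, and they are asserted by the test suite.

Absolute numbers are not patient-specific: the geometry is idealized,
the circulation parameters are representative, the pump map is
synthetic, and the active-law constants are literature defaults. The
model also omits atria (diastolic filling dynamics are simplified),
valve structures, inertia, fluid–structure interaction, viscoelasticity
and growth/remodeling. Pump-on sweep beats are run for two cycles from
a calibrated start and retain a few ml of beat-to-beat drift (logged);
trend directions are insensitive to this, absolute Table-style values
at high speed would not be.

## Problem sizes and tolerances

Default mesh: 12×5(+apex)×2 LV / RV shell, 192 hexahedra, 309 nodes
(~930 dof); reduced test mesh 80 hexahedra. Newton: relative force
residual 1e-8 with line search; coupling residual 0.05 ml per cavity;
circuit Newton 1e-11 relative. Calibration runs use 20 ms coupled steps
and two-cycle beats; confirmation runs three cycles. All computations
are deterministic for a fixed configuration; the only randomness in the
package is the optional noise in synthetic calibration datasets, which
takes an explicit seed.
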