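# Methods

## Scope and model

`hydrodipole` analyses the dipolar response of a solvated protein under a
uniform applied electric field E(t) = E_max·cos(ωt)·ê (or a static field),
as sampled by molecular-dynamics trajectories: hydration-shell
decomposition, collective dipole time series, dipole autocorrelation and
relaxation times, and the phase lag of the response behind the field. The
package does not run MD; it consumes trajectories (standard formats via
MDAnalysis, or its own lossless `.npz` dialect) plus a topology carrying
per-site partial charges and molecule classes.

Field intensities are specified as root-mean-square values in V/Å. For a
cosine waveform the peak is E_max = √2·E_rms (the rms of a cosine over
whole periods); a static field's constant strength equals the quoted rms
value. The field direction defaults to the laboratory x axis, and all
dipole observables are x components by default. `phase_origin` (default:
trajectory time zero) fixes where the cosine argument vanishes; lag times
are reported relative to it. The field's phase at production start is a
convention of the analysis, not a property of the data.

Units throughout: Å, ps, e, Debye, V/Å, GHz, K. Conversion constants
(1 e·Å = 4.80321 D; k_B·300 K = 0.025852 eV; 1 D·(V/Å) = 0.2081943 eV;
k_C = 14.3996 V·Å/e) were re-derived from CODATA values.

## Hydration shells and volumes

The "protein surface" is operationalized as the set of protein heavy atoms
(site mass > 3 g/mol); a water's surface distance is the minimum-image
distance from its oxygen to the nearest such atom. This is the simplest
reproducible metric consistent with a 2.25 Å first-shell boundary; solvent
accessible surface constructions are deliberately out of scope. Default
boundaries: shell1 d ≤ 2.25 Å, shell2 2.25 < d ≤ 6 Å, bulk beyond; both
configurable and held fixed across field conditions.

Voronoi volumes use a rectangular-periodic tessellation: seeds (water
oxygens plus protein heavy atoms, so protein volume is never attributed to
water) are wrapped into the box and surrounded by their 26 periodic images;
each central cell is then bounded and its volume is the convex hull of its
vertices. The cells partition the box exactly — the volume-closure
assertion (0.1%) is checked on every tessellated frame. Cost grows as the
Voronoi diagram of 27·N points; intended for 10²–10⁴ seeds per frame.

Density profiles are Voronoi-normalized: a bin's density is
(count × 18.0153 g/mol / N_A) / (sum of the member waters' cell volumes).
Empty bins report zero. Per-bin ratios are noisy at realistic bin
occupancies (the relative spread of a single Voronoi cell volume in a
Poisson medium is ≈ 40%), so `DensityProfile` retains per-bin counts and
volumes and `pooled_density` forms the mass-weighted estimate over a
distance range — the estimator used for far-field (bulk) density checks.

The intrinsic electrostatic field at a hydration-water oxygen is the bare
minimum-image Coulomb sum over all protein partial charges (no cutoff, no
Ewald, no reaction field). It is a local-field diagnostic, adequate for
distributions of |E| at Å-scale distances where the nearest charges
dominate; it is not a substitute for the full periodic electrostatics of
the underlying simulation.

## Dipoles

Molecules are made whole by minimum-image unwrapping about their first
site before any Σq·r evaluation (broken molecules corrupt dipoles).
Neutral-molecule dipoles are origin-independent; the protein (net charge
+8 e for hen egg-white lysozyme at pH 7, reproduced by residue counting in
`protein.formal_charge_at_ph7`) is referenced to its centre of mass, making
the reported protein dipole translation-invariant. Counterions belong to no
dipole group. Shell-group membership is re-resolved per frame from the
shell assignment, so waters migrate between groups as they do physically.

## Relaxation and lag estimators

The ACF estimator averages over all valid time origins (FFT-based, unbiased
1/(n−k) normalization). Detrending by the series mean is the default: under
a static field the mean dipole is nonzero and the ACF is meant to measure
fluctuation relaxation; `detrend="none"` is available for signals whose
structure lives in the mean (a driven cosine has C(τ) = cos(ωτ)).
Relaxation times come from a least-squares single-exponential fit
C(τ) ≈ exp(−τ/τ_rel) over a configurable window, seeded by a log-linear
slope; a stretched or multi-exponential shape is summarized by whichever
regime the window selects, which is why the fit window is always reported
alongside τ. ACFs from separate windows can be averaged (`average_acf`).

The lag estimator fits M(t) = A·cos(ω(t − t_lag)) + c by linear least
squares in quadrature form (robust to noise, unlike peak picking), reduces
t_lag modulo the period into [0, period), and flags fits whose amplitude is
within two standard errors of zero as degenerate. Physically Debye-like
responses put t_lag in [0, period/4]; the estimator does not enforce this.
Lag can be fitted per whole series or per window; both modes are exposed.

## Windows and the condition matrix

Analysis windows shift by an integer number of field periods so every
window starts at the same field phase. The default shift is the smallest
integer multiple of the period ≥ 2000 ps (2000 ps flat for static/zero
fields); the resolved shift is snapped *down* to the sampling grid, so a
100 ns run in 10 ns windows at 2.45 GHz (period 408.16 ps, five periods →
2040 ps on a 1 ps grid) yields 45 overlapping windows. Snapping introduces
a sub-sample phase misalignment between consecutive windows (< ω·Δt),
which accumulates across distant windows; lag comparisons should therefore
prefer nearby windows or exact-period sampling grids.

A window is retained when the tracked shell's composition matches its
first-frame reference in at least 90% of frames (inclusive). "Matches"
defaults to exact set membership; a Jaccard-similarity threshold < 1
relaxes it. The 90% level and first-frame reference are documented
conventions.

The condition matrix expands {zero field} ∪ {static intensities} ∪
{frequencies × intensities} over box/salt setups; the reference design
(3 static, 3×3 oscillating, 2 setups) yields 26 conditions.

## The synthetic rotor generator

The generator replaces full MD for testing with the minimal model that
preserves the observables the pipeline measures: N independent point
dipoles of moment μ (default 2.3 D, water-like) whose orientations u obey
overdamped rotational Brownian motion at temperature T (default 300 K)
with rotational diffusion coefficient D_r. One Euler–Maruyama step rotates
u by the deterministic drift (μ·D_r/k_BT)·(E − (u·E)u)·dt plus isotropic
tangent-plane Gaussian noise of variance 2·D_r·dt per axis, then
renormalizes. A guard rejects steps whose deterministic rotation could
exceed 0.1 rad. Identical seeds give bitwise-identical output.

Closed-form oracles: static-field alignment ⟨cos θ⟩ = L(μE/k_BT);
free-rotor rank-1 orientational ACF exp(−2·D_r·t), hence collective-dipole
relaxation time 1/(2·D_r); driven-rotor lag arctan(ωτ)/ω in the
linear-response regime. The first-order scheme carries an O(D_r·dt)
equilibrium bias (measured ≈ +0.5·D_r·dt on ⟨cos θ⟩), so oracle
comparisons use D_r·dt ≲ 0.004, where the bias is well below the
statistical resolution of the test ensembles.

`emit_trajectory` renders orientations as rigid 3-site neutral molecules
(O–H geometry 0.9572 Å / 104.52°, charges scaled so the molecular dipole
is exactly μ along u) on a lattice or at user positions, producing a
`Trajectory`/`Topology` pair for the coordinate-space pipeline;
`uniform_water_box` builds single-frame bulk-density boxes around a probe
site for tessellation and density fixtures.

An optional per-rotor static `intrinsic_field` emulates the strong
protein-generated field felt by first-shell waters. Its effects in this
model, established both by simulation and by an exact finite-volume
solution of the 1-D Smoluchowski operator: a bias of reduced strength
ξ = μE_int/k_BT suppresses the driven oscillation amplitude (the
fluctuation variance available to the drive shrinks), and *accelerates*
orientational relaxation — the lowest longitudinal relaxation rate rises
from 2·D_r at ξ=0 to ≈ 2.8·D_r at ξ=2, and grows further with ξ, because
the polar potential −μE_int·cos θ has no barrier. Consequently biased
rotors show a *shorter* field-phase lag and a *smaller* fitted τ than free
rotors at matched D_r. The slow dynamics of real bound first-shell water
arises from hydrogen-bond-constrained rotational mobility, i.e. an
effectively smaller D_r, which this generator models directly through its
D_r parameter rather than through the bias field. Tests that probe the
bias-field orderings state the expected directions explicitly; the
amplitude suppression holds, the slowing does not, and the acceptance
report publishes the measured biased/free ratios as computed.

## Test problem sizes

Oracle comparisons are sized so statistical resolution, not wall time,
sets the precision: alignment checks use 2000 rotors × 150 ps at
dt = 0.02 ps (3-standard-error agreement with L(x)); lag recovery 5000
rotors × 20 periods at 10 GHz (15%); relaxation 800 rotors × 5 ns (10%);
tessellation fixtures use 8–150 seeds; density checks pool the full far
region (≥ 5 Å) of two 40 Å bulk boxes (≈ 0.2% estimator spread against a
5% band). The full suite runs in a few minutes on one CPU.

## Known limitations

- Rectangular periodic boxes only (minimum-image throughout); triclinic
  cells are not supported.
- The Voronoi tessellation tiles all 26 images rather than a shell of
  nearby ones; fine at fixture scale, wasteful for very large frames.
- The intrinsic-field diagnostic ignores periodic electrostatics beyond
  minimum image.
- The rotor model freezes translation: no shell exchange, no
  hydrogen-bond network, no inertial or polarizable dynamics. Passing
  oracle tests validates the estimators, not the realism of any particular
  MD system.
- Single-exponential relaxation fits summarize multi-exponential ACFs only
  within the chosen fit window.
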