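# Methods

## Scope and model

`scmem` analyzes planar coarse-grained bilayers of the stratum-corneum
(SC) type: cholesterol (CHOL, SP1 head bead), the ceramide
N-stearoylsphingosine (DPCE, P1 head bead, sphingosine chain A and
fatty-acid chain B), behenic acid (BCN, charged Qa head bead), optionally
linoleic acid (LA), solvated in polarizable-water beads optionally mixed
with ethanol.  Internal units are nm / ps / kJ mol⁻¹ (GROMACS-family
conventions); conversions to ångström (thickness), cm² s⁻¹ (diffusion) and
kcal mol⁻¹ (free energies, 1 kcal = 4.184 kJ) happen at output boundaries
only.  k_B is fixed at 0.0083145 kJ mol⁻¹ K⁻¹ and the default temperature
at 320 K (k_BT = 2.661 kJ mol⁻¹).

The built-in species registry carries labels, head-bead names, chain
connectivity and per-bead charges; it is bookkeeping for the analyses,
not a force field.  Bead layouts are schematic (one hydrophilic head bead
plus apolar tail beads); analyses that depend only on labels and
geometry — all of them — are unaffected by this simplification.

## Composition arithmetic

Lipid counts split an integer total by an integer ratio with the
remainder assigned to the ceramide (so 625 lipids at 1:1:1 give
208/209/208, the canonical three-component SC patch).  The LA count in
18:18:18:5 systems is `floor(n_CHOL · r_LA / r_major)` (57 for 208 CHOL) —
the only rounding rule consistent with the published count tables.  The
"50% molar" ethanol solvent is an equal split of solvent *beads*, one
polarizable-water bead counting as one solvent unit; the ethanol count is
`round(fraction · beads)` (half-to-even).  Ion counts are explicit inputs:
the published Na⁺/Cl⁻ counts of the reference systems are not reproducible
from neutralization plus 0.15 M arithmetic, so no derivation is attempted
and the composed net charge is reported as-is.

Initial placement uses jittered lattices: per-leaflet 2-D lattices for
lipids (per-species leaflet difference ≤ 1; head beads at ±z_leaflet,
default 1.2 nm, chains stacked toward the midplane ending 0.25 nm short of
it) and a 3-D lattice for solvent/ions/tracers outside the slab
|z| < z_leaflet + 0.5 nm.  Lattice spacing guarantees a minimum
*inter-molecular* bead distance of the exclusion radius (default
0.45 nm); beads within one molecule sit at the chain spacing, which is
bonded geometry, not packing.  Placement is deterministic per seed.

## Synthetic dynamics

The generator integrates the overdamped (position) Langevin equation by
Euler–Maruyama:

    x ← x + (D / k_BT) F(x) dt + sqrt(2 D dt) ξ,   ξ ~ N(0,1)

with per-species diffusion constants D (nm² ps⁻¹); species without a D are
frozen.  There is no inertia, thermostat, or pairwise non-bonded force:
the analyses consume positions and pull forces only, and this choice makes
the ground truth (D, the external profile U(z), bond-orientation laws)
exact by construction.  Potential terms are analytic test-harness pieces:
harmonic z-tethers, lateral site tethers, a 1-D profile U(z) as a sum of
Gaussians, linear ramps, harmonic bonds and angles (minimum-image
displacements throughout).

Numerical guards: one RNG stream in bead-major order with a mandatory
seed (bitwise reproducibility); a stability validator rejecting timesteps
with `D·k·dt/k_BT > 0.5` for the stiffest harmonic term (the
Euler–Maruyama damping factor 1 − a must stay well inside (0, 1); the
spring-relaxation criterion, not a raw length-scale rule, is what governs
stiff harmonic modes) and requiring `D·dt ≤ (0.1 w)²` for the narrowest
Gaussian width w; a runtime instability error if any step displacement
exceeds half the smallest box length.  Frames are saved every
`save_every` steps (default 10) so the saved-frame interval is well
separated from the integrator step.

The steered pull moves a harmonic spring center at constant speed,
`z_c(t) = z₀ + direction · v · t`, records the instantaneous force
`F = k (z_c − z)` at every saved frame (time-aligned with the
trajectory), and tracks the tracer's z unwrapped so the spring force is
well defined under periodic boundaries.  Protocol defaults are
k = 2000 kJ mol⁻¹ nm⁻² and v = 1 × 10⁻⁵ nm ps⁻¹; the pull acts along z
only, with xy unrestrained.  Multiple tracer indices run as
non-interacting replicates inside a single integration.

The bond-orientation sampler emits two-bead probe molecules whose bond
vectors follow a delta distribution at polar angle θ (azimuth uniform),
the uniform law on the sphere, or a von Mises–Fisher axial law of
concentration κ (inverse-CDF sampling of the polar angle) — controlled
ground truth for the order-parameter estimator.

## Structural analyses

Frames are re-centered per frame (reference: all membrane beads by
default) so the bilayer midplane sits at z = 0, removing normal drift.
Density profiles histogram selected bead z positions (default bin width
0.1 nm), dividing per frame by the bin volume `bin_width · L_x · L_y`;
beads are re-wrapped about the midplane so the profile integrates back to
the mean selected bead count exactly (conservation is tested at 10⁻⁹
relative).  The y-axis is number density (beads nm⁻³) by default; mass
weighting (amu nm⁻³) is an option, and output columns are labeled with
the convention.

Leaflet assignment is the sign of each molecule's head-bead z in the
centered frame; molecules within 10⁻⁶ nm of the midplane fall back to the
sign of their chain-end bead.  The interleaflet distance per component is
`|⟨z⟩_upper − ⟨z⟩_lower|` of the head beads, per frame, reported in Å;
by default the final 50% of frames enter the average (equilibration
discard; configurable, and set to 1.0 throughout the validation studies,
whose constructions are stationary).

Order parameters use the fixed z axis as the membrane normal (the systems
are planar; no local-normal estimation) and minimum-image bond vectors,
so wrapped coordinates are tolerated.  Zero-length bond vectors are
excluded from the average with a logged count; a bond with every sample
excluded is an error.

## Diffusion estimation

Lateral coordinates are unwrapped by accumulating minimum-image
inter-frame displacements (an inter-frame displacement reaching half the
box is ambiguous and raises).  Center-of-mass drift is removed by
subtracting the per-frame mean lateral displacement of the reference
selection.  MSD(τ) is averaged over molecules and *all* time origins via
the FFT (Wiener–Khinchin) algorithm; correlated origins are accepted, and
dispersion is computed across molecules, matching how per-component error
bars are customarily drawn.  D = slope/(2d), d = 2, from an unweighted
least-squares line over lags in [10%, 50%] of the maximum lag (skipping
short-lag correlation and long-lag noise); the conversion is
1 nm² ps⁻¹ = 10⁻² cm² s⁻¹ (10⁻¹⁴ cm² / 10⁻¹² s).  A curvature diagnostic
compares the slope over the two window halves and flags relative
differences above 25% — it fires on ballistic drift (MSD ∝ τ²) and
confinement, the two failure modes a slope fit would silently mis-read.
The headline mean is the raw cross-molecule mean (no flooring of negative
per-molecule slopes); d = 3 is available for solvent QC.

In the recovery study the MSD is computed to 10% of the run length: the
variance of time-averaged MSD grows like lag/T, so short lags carry
nearly all the information, and the short window keeps the estimator's
relative error near 1% at 500 molecules × 5000 frames.

## PMF estimation

`W(z(t_k))` is the cumulative trapezoid of F dz along the *spring-center*
schedule (stiff-spring mapping: well defined even when the tracer lags,
and exactly the "integrate the instantaneous force over the constant-speed
schedule" estimator).  Work samples are binned onto a uniform grid
(default 0.05 nm) by per-bin mean; empty interior bins are linearly
interpolated and flagged, empty edge bins trimmed.  Profiles are anchored
to zero over a bulk reference region (default: the outermost 0.5 nm on
the side where the pull began) and replicates averaged arithmetically —
no Jarzynski exponential reweighting, matching the single-slow-pull
estimator the package implements; the friction bias of a finite pull
speed is *reported* as the bound γ·v·L (γ = k_BT/D) rather than
corrected, and forward/backward pulls over a symmetric landscape should
agree within it.  No leaflet symmetrization by default (single-direction
pull); an averaging flag exists.  Descriptors: the entry barrier is the
maximum anchored W on the path from the bulk-side edge to the interior
minimum (clipped at 0), the global minimum depth the lowest W inside the
stated membrane-interior interval.

## Validation studies (synthetic ground truth)

The observables these tools exist for are normally computed from
microsecond coarse-grained trajectories of ~700-lipid patches; those are
not recomputable at desk scale.  Validation therefore closes the loop on
synthetic data with exact truth, at problem sizes chosen once:

- **Diffusion recovery**: 500 single-bead molecules, 5000 saved frames at
  1 ps spacing (10 integrator steps per frame), periodic 10 nm box, over
  D ∈ {0.01, 0.05, 0.2} nm² ps⁻¹; full unwrap → MSD → fit pipeline.
  Expected relative error ~1% (observed 0.2–0.6%), against a 5% band.
- **PMF recovery**: the test landscape is a 1.0 kcal/mol Gaussian barrier
  at z = 1.0 nm (width 0.3 nm) over a −2.0 kcal/mol well at z = 0 (width
  0.7 nm) — the entry-barrier-plus-interior-minimum shape of a permeant
  profile.  Tracer D = 0.005 nm² ps⁻¹, dt = 0.02 ps, pull from 2.5 to
  −0.5 nm, k = 2000 kJ mol⁻¹ nm⁻², speed ladder 2×10⁻³ / 1×10⁻³ /
  5×10⁻⁴ nm ps⁻¹ (halved twice), 64 replicates at the slowest rung with
  equal-compute allocation (replicates ∝ v).  The allocation follows from
  the noise analysis: per-replicate work noise has variance
  2 γ k_BT v L, so replicate means at R ∝ v have a speed-independent
  noise floor and the ladder isolates the friction bias γvL — RMSD then
  decreases monotonically with speed and sits near 0.1 kcal/mol at the
  slowest rung, with barrier/depth errors well inside 0.3 kcal/mol.
- **Order parameters**: aligned and in-plane delta ensembles hit S = 1
  and −0.5 exactly; a δ(θ) grid matches ½(3cos²θ − 1) to ~10⁻¹⁵; an
  isotropic ensemble of 10⁶ bonds gives |S| ≲ 5×10⁻⁴ (sampling sd
  sqrt(1/5n)).
- **Thickness**: Gaussian leaflets (means ±1.2 nm, σ = 0.15 nm, 200
  molecules × 100 frames) read 24.0 Å; point masses at ±1.239 nm read
  24.78 Å to machine precision.
- **Work integration** is checked against an independent cumulative
  trapezoid on random traces at machine precision.

`scripts/acceptance.py` reruns all of the above from one seed and writes
the measured numbers as JSON.

## What the synthetic data does and does not emulate

The generator reproduces the *statistical structure* the estimators rely
on: Brownian lateral motion at prescribed D, leaflet geometry with
Gaussian spread, prescribed bond-orientation laws, and pull-force traces
whose work converges to a known U(z).  It does not emulate molecular
packing, collective lipid motion, hydrodynamic or Saffman–Delbrück
finite-size effects, anomalous short-time diffusion, membrane
undulations, or solvent structure.  Passing the validation suite
therefore certifies the *estimators* (unbiasedness, units, windows,
convergence behavior), not the realism of any particular membrane model;
applied to real trajectories the same estimators inherit those systems'
physics.

The scaffold potential of the demo pipeline (z-tethers + chain bonds +
weak angle springs) keeps leaflet architecture and solvent partitioning
but leaves chains nearly orientationally disordered — its order
parameters are expected to sit near zero, and the controlled
orientation sampler is the right ground truth for that estimator.

## Known limitations

- The PMF estimator is the single-direction constant-velocity work
  integral; no umbrella sampling/WHAM, no bootstrap error bars
  (replicate sd only), no 2-D profiles.
- Diffusion fits are unweighted least squares (no GLS across correlated
  lags) and report no anomalous-diffusion exponent.
- The placement routine produces analyzable starting geometry, not
  energy-minimized packing.
- GRO parsing follows the fixed-column dialect; TPR/PDB/.itp files are
  out of scope, and XTC writing is not provided (reading goes through the
  MDAnalysis adapter).
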