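# Methods

## The restraint model

A coarse-grained peptide is represented by one backbone bead per residue.
Two internal coordinates control secondary structure: the bend angle
θ over each consecutive bead triple (i, j, k), defined as the arccosine of
the normalized dot product of the arm vectors j→i and j→k, and the
dihedral φ over each quadruple (i, j, k, l), defined through the
four-quadrant arctangent with the IUPAC sign convention (planar cis = 0°,
trans = 180°; reflecting the l bead through the i,j,k plane flips the
sign).

Each coordinate x carries an inverted-Gaussian well

    V(x) = −K · Σ_c exp(−(x − c)² / σ),

where the sum runs over the well center and, for dihedrals, its two
periodic images at center ± 360°. Conventions and parameters:

- **x in degrees.** All restraint arithmetic is carried out in degrees,
  matching how the centers and σ are conventionally quoted; the
  degree↔radian conversion lives entirely in the geometric gradient
  dx/dr, so V and dV/dx never mix units.
- **σ (width), default 14.** σ divides the *squared* degree deviation, so
  the effective 1-σ width of the well is √(σ/2) ≈ 2.6°. σ is exposed as
  the plain printed scalar rather than being squared internally; the well
  shape is what matters, and the analysis results are insensitive to this
  choice over the tested range (a σ = 114 control behaves consistently).
- **K (depth), default 50 kJ/mol.** The depth of one well. There is no
  single canonical value; 50 kJ/mol puts the restraint on the scale of CG
  bonded interactions (kT at 310 K is 2.58 kJ/mol, so the well is ~19 kT
  deep and thermally rigid). Everything downstream is parameterized in K.
- **Centers.** θ_min = 96°, φ_min = 60° define the α-helical basin;
  θ_min = 124°, φ_min = 100° the extended-disordered basin. A chain of n
  residues gets n−2 bend and n−3 dihedral restraints.
- **Periodic images.** The three-center construction keeps V(φ)
  continuous across the ±180° boundary; at σ = 14 the image terms are
  numerically zero except within a few degrees of the boundary, which is
  exactly where they are needed.

The sign convention deserves a note: a Gaussian *well* requires the
negative exponent, V = −K·exp(−Δ²/σ); with a positive exponent the
expression is unbounded below and restrains nothing. This package
implements the well form, and its forces F = −dV/dx·dx/dr are validated
against central finite differences (relative error ≤ 10⁻⁵ on 1000 random
poses) rather than against any printed formula. Per-restraint force sums
and torques vanish identically, as they must for an internal-coordinate
potential.

Degenerate geometry (coincident beads, collinear triples) raises an
error; silently returning 0° or 180° would propagate NaN forces.

## Tabulated export

Any restraint can be tabulated as three whitespace-separated columns
(angle in degrees, V in kJ/mol, −dV/dx in kJ/mol/deg) on a uniform grid
over [0°, 180°] (bends) or [−180°, 180°] (dihedrals), the dialect used
for tabulated bonded interactions by mainstream MD engines. The force
column is analytic; its agreement with the *numerical* derivative of the
energy column is limited by central-difference truncation error, which at
0.1° spacing is ≈ K/5000 near the well shoulders — the 10⁻³ kJ/mol/deg
consistency budget is met for wells up to ~5 kJ/mol and scales linearly
in K.

## Toy samplers

The internal-coordinate Metropolis sampler walks the scalar angle with
uniform symmetric proposals (bend proposals outside (0°, 180°) are
rejected; dihedrals wrap). Because the angle itself is the sampled
variable, its stationary law is exactly exp(−V/kT) with no Jacobian, and
the quadrature Boltzmann CDF is an exact oracle: Kolmogorov–Smirnov
distances stay below 0.02 at 10⁵ retained samples (thinning 10).

The Brownian-dynamics integrator is first-order overdamped Langevin,
r ← r + μFΔt + √(2μk_BTΔt)·ξ, with mobility μ = 0.01 nm²/(kJ/mol·ps) and
k_B = 0.0083145 kJ/mol/K. Cartesian sampling induces a sin θ measure on
bend angles, so Brownian results are compared against the sin-corrected
density — at K = 50 the correction shifts the mean bend by under 10⁻³
degree and is negligible. Stability requires μ·k_eff·Δt ≪ 1; the angle
wells are stiff in Cartesian terms (k_eff ~ 2·10⁵ kJ/mol/nm² at K = 50,
σ = 14), so the demonstration trajectories use Δt = 10⁻⁴ ps. The sampler
validates restraints; it makes no claim about binding thermodynamics (no
solvent, no membrane, no barostat).

## Contact metrics

A residue contacts the membrane in a frame when the minimum-image
distance from its backbone bead to the nearest phosphate bead is ≤ 1 nm
(the boundary is inclusive, fixed so tests are exact; backbone beads play
the role of Cα positions in the one-bead-per-residue mapping; phosphates
of both leaflets are eligible). Distances use the orthorhombic
minimum-image convention; triclinic boxes are rejected. Averaging the
binary contact record over frames gives per-residue contact indices;
averaging those over a window gives the GCI. Segment errors split frames
into three consecutive blocks (earlier blocks absorb remainders — a
deterministic rule) and report the population standard deviation of the
per-block GCI.

Tm is extracted as the midpoint of a least-squares 4-parameter logistic
b + (a−b)/(1 + exp((T − Tm)/s)) fitted to the melting curve (scipy
`curve_fit`, plateau/steepness bounds, tight tolerances so an exact
logistic is recovered to ~10⁻⁸ K). Curves that do not drop by at least
0.2, or that increase with temperature, raise a no-transition error; a
half-range crossing estimator is exposed as a robust fallback for noisy
curves. TAGCI averages the windowed GCI (15 residues from the construct's
first residue) with equal weights over the temperature ladder.

## Synthetic campaigns

The generator models *occupancy*, not physics. Each residue r is an
independent two-state Markov chain with stationary bound probability
p_r(T) = w_r / (1 + exp((T − Tm)/s)). Defaults are the study conditions
throughout: Tm = 380 K (mid-ladder), steepness s = 10 K (the transition
spans roughly half the 310–450 K ladder), 15 temperatures at 10 K steps,
and an N-terminal-dominant weight profile w = 1 for residues 1–7 then
linearly 0.95 → 0.24, whose mean of 0.69 reproduces the plateau GCI
characteristic of extended-disordered anchoring; a uniform profile
(helical-like, complete binding at low T) is one call away. The
helical-vs-extended contrast is emulated by two campaigns with true Tm
410 K vs 350 K — a 60 K shift placed symmetrically in the ladder.

Kinetics: with total relaxation rate c = k_on + k_off_base (default 0.1
per frame), each frame the state refreshes from Bernoulli(p) with
probability c and persists otherwise. This keeps the stationary
distribution exact for any p ∈ [0, 1] (p = 0 and p = 1 are absorbing),
gives frame-to-frame autocorrelation 1 − c (correlation time 10 frames),
and therefore exercises the segment-based convergence errors on
genuinely correlated data.

Rendering places phosphates on a planar grid (z = 0, spacing 0.7 nm) in a
5.6 × 5.6 × 14 nm box and puts each residue's (x, y) on a grid node, so
its minimum phosphate distance equals its own height exactly. Bound
heights are drawn from a Gaussian at 0.5 nm truncated to
[0.05, 0.95] nm; unbound at 1.6 nm truncated to ≥ 1.05 nm (jitter
σ = 0.12 nm). The 0.05 nm guard bands on both sides of the 1 nm threshold
make the states → frames → contact-matrix round trip bit-exact, which is
what lets every downstream metric be checked against generator truth.

What the generator does *not* emulate: real lipid dynamics, cooperative
binding between residues (residues are independent), insertion depth,
membrane curvature, or any force-field energetics. Passing tests
therefore demonstrate that the *analysis stack* is correct and that
melting parameters are recoverable at realistic sampling depths — not
that any particular force field reproduces them.

## Numerical choices and limitations

- Finite-difference validation uses central differences, step 10⁻⁶ nm
  (forces) and 10⁻⁴ deg (internal gradients), relative tolerance 10⁻⁵ on
  a max(1, |F|) scale.
- Random poses for force validation are fixed-seed bond-length-preserving
  random walks (0.35 nm bonds); near-degenerate poses that raise are
  redrawn.
- Metropolis proposal half-width 2° gives ~45% acceptance in the default
  wells; all samplers draw their randomness from a single NumPy
  generator per run, so every result is reproducible from one seed.
  Campaign rungs use `SeedSequence.spawn`, so temperatures get
  independent streams derived from the one campaign seed.
- Analysis problem sizes used in the validation suite: 5000 frames per
  temperature rung and 20 replicate seeds for parameter recovery, 10⁵
  retained Metropolis samples per distribution check. At these depths the
  fitted Tm lands within 3 K of truth and the 60 K design shift is
  recovered within 4 K.
- The logistic fit assumes a single two-state transition; multiphasic
  melting curves are out of scope (the fallback crossing estimator still
  returns a midpoint but neither estimator models multiple transitions).
- Contact analysis treats frames as given; it performs no alignment,
  imaging or leaflet assignment.
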