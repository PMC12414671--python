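# Methods

This note documents the models implemented in `lh2bend`, their
assumptions, the tunable parameters and their defaults, and the numerical
choices made where the design was genuinely open.

## 1. Ring geometry

The B850 aggregate is modelled as 18 point pigments (9 α/β dimers) on a
ring of radius r0 = 3.8 nm (half of the ~76 Å cylinder diameter of LH2),
each carrying a unit Qy transition dipole.  The parametric builder places
sites at equal angular spacing with dipoles in-plane, nearly tangential,
alternating by ±10° about the local tangent.  The alternation angle is
the dimerization stand-in: published coupling and orientation
parameter sets for the ninefold complex vary, so the default is
configurable.  Two consequences of this pattern matter downstream:

* the lowest exciton state of the ideal flat ring is strictly dark
  (its alternating-sign coefficient pattern is orthogonal to the ring's
  in-plane dipole harmonics), and
* under bending, the alternating radial dipole components acquire z
  projections that add coherently in the lowest state, producing the
  quadratic brightening law fz ∝ Δz².

A PDB path (`ring_from_pdb`) extracts the ring from a standard file:
BCL residues with Mg/NB/ND atoms, the 18 residues closest to the common
best-fit plane (this separates B850 from the out-of-plane B800 ring),
positions from Mg (Å→nm), Qy dipoles along NB→ND, and alignment of the
best-fit plane to z = 0.  Fixed-column PDB coordinates quantize at
0.001 Å, so round-trip radii are reproducible to ~2·10⁻⁴ nm, not better.

Deformations:

* **Elliptical** (correlated disorder): semi-axes a = r0(1+ε),
  b = r0(1−ε) with ε = δr/r0; sites re-placed at *equal arc length*
  (preserving nearest-neighbour spacing, consistent with the
  length-preserving philosophy), dipoles keeping their angle to the local
  tangent.  Default standing amplitude ε = 5.7 %, the value required to
  match single-molecule spectra of free LH2.
* **Cocurvature**: length-preserving map onto a sphere of diameter d —
  planar radial distance s becomes arc length (polar angle θ = s/R),
  azimuths preserved, dipoles rotated into the local tangent plane.
  The recorded Δz is the exact sagitta R(1 − cos θ_max) ≈ r0²/d; the
  mechanics layer's closed form uses the conventional thin-shell
  approximation r0²/(2d).
  The constant factor between the two is absorbed into fitted prefactors;
  only the 1/d scaling is normative downstream.
* **Plate deflection**: site z set to −w(s) from an axisymmetric
  deflection profile, dipoles tilted by the local slope dw/ds.

## 2. Exciton model

The Frenkel Hamiltonian carries uniform mean site energy E0 =
12 300 cm⁻¹ and nearest/second-neighbour couplings; defaults
t_intra = 300, t_inter = 230, t_second = −50 cm⁻¹ are configurable
stand-ins at the literature scale.  All headline results are scale-free (slopes, ratios, linearity)
and do not depend on the absolute coupling scale.

**Deformation-dependent couplings.**  When geometry changes, couplings
follow the point-dipole interaction κ/r³ (κ the orientation factor),
calibrated *per bond* against the undeformed reference ring so the
reference reproduces the fixed values exactly.  A single global prefactor
cannot reproduce two different nearest-neighbour couplings from a
geometry whose bonds are mirror-equivalent, hence the per-bond scheme.

**Correlated disorder acts on site energies too.**  Elliptical
deformation modulates each site energy in proportion to its local radial
strain, Eₙ = E0 + k·(sₙ − r0)/r0, with k = 2500 cm⁻¹ per unit strain by
default (±140 cm⁻¹ at the 5.7 % standing ellipticity — comparable to the
random-disorder widths).  Rationale: with a purely geometric ellipse the
disorder-averaged lowest-state fxy is an even function of ε (ε → −ε is a
90° rotation, statistically equivalent under isotropic disorder) and
therefore quadratic near zero; pigment site energies are in reality
strongly strain-sensitive, and at this coupling scale the correlated
channel operates in the strong-mixing regime whose response is linear in
ε over the studied 0–10 % range — the behaviour the lifetime analysis
builds on.  The dark-state limit, the sum rule and fz ∝ Δz² are
insensitive to k (for cocurvature from a circular ring the strain is
zero by construction).

**Random disorder.**  Independent Gaussian offsets on the diagonal,
width Γ interpreted as the FWHM of the site-energy distribution by
default (the common convention in the LH2 disorder literature; standard
deviation selectable).  Typical widths: Γ = 125 and 370 cm⁻¹.  Seeding is
counter-based — realization i draws from `default_rng([seed, i])` — so
ensembles are reproducible and order-independent.  Ensemble averages of
the lowest-state fz/fxy (lowest eigenvalue per realization, no thermal
weighting) are computed by batched dense diagonalization; Monte-Carlo
standard errors accompany every mean.

The bending sweep default covers sphere diameters 54–550 nm — the size
span of the study — giving a full decade of Δz (≈ 0.03–0.3 nm).  Across
it, mean fxy varies by only a few percent (bending and in-plane
deformation decouple); mean fz follows Δz² with log-log slope 2.00.

## 3. Plate mechanics

* **Critical diameter** (in-plane): the Coulomb pull of the charged
  sphere has in-plane components at the ellipse axis endpoints; the
  imbalance circularizes the plate above
  d_c = a0·[((b0/a0)^{2/3} − (b0/a0)²)/(1 − (b0/a0)^{2/3})]^{1/2}
  (= 13.7 nm for a0 = 11.0, b0 = 8.5 nm; analytic limit a0√2 at
  b0 = a0, evaluated via the limit inside a 10⁻⁹ neighbourhood).
* **Force profile convention**: the particle's charge (∝ ρd²) is treated
  as an effective point source at depth h = d + standoff below the plate
  plane, giving F∥(s) = Q·s/(s² + h²)^{3/2}.  This is the depth
  convention under which the in-plane balance occurs exactly at the
  critical diameter above; a point charge at the geometric sphere center
  (depth d/2) would place the crossover at twice that value.  The angles
  θ₁, θ₂ are measured between the plate plane and the source-to-endpoint
  lines.  Forces are in dimensionless model units — only ratios and
  crossovers are meaningful.
* **Kirchhoff plate** (out-of-plane, small particles): axisymmetric
  D∇⁴w = 0 with a center point support (w(0) = 0, regular slope), the
  rim shear balancing the support reaction, and a moment-free rim
  (Poisson ratio ν = 0.3 default).  The admissible basis reduces to
  w(r) = r²(c₁ + c₂ ln(r/r0)) with c₂ = −q r0/(4D),
  c₁ = −c₂(3+ν)/(2(1+ν)), so w_max = q r0³(3+ν)/(8D(1+ν)) — linear in
  the load q and inversely linear in the rigidity D.  Deflections beyond
  10 % of the plate diameter trigger a small-deflection warning.
* **Residual check**: `biharmonic_residual` applies fourth-order central
  differences for w′…w′′′′ in 80-bit extended precision on an
  exact-step interior grid and normalizes the assembled operator by its
  largest term.  (Implementation notes: `np.linspace` does not produce
  exactly uniform long-double grids, and stencil weights must be formed
  as integer ratios in extended precision; both effects otherwise
  dominate the residual.)  The solution's residual is ~2·10⁻⁹.
* **Surface charge**: ρ = c/d with a configurable coefficient; the
  small-particle deflection Δz = P·ρ/(1 + 4r0²/d²)^{3/2} then peaks at
  d = 2√2·r0 ≈ 10.7 nm, below the studied size range, so the region-3
  rate is monotone decreasing on 15–80 nm.

## 4. Lifetime link

Radiative and nonradiative rates are linearly related for this class of
emitter, so the total rate remains proportional to the lowest-state
oscillator strength: f ∝ k_r + k_nr = 1/τ.  The proportionality is
anchored so a reference state (free LH2) maps to τ = 1.3 ns; the
linear-relation coefficients (slope ratio, offset) default to zero and
only rescale the anchor.  Composing the deflection laws with fz ∝ Δz²
yields the fitting forms with an added baseline (a pure proportionality
cannot produce a plateau):

* region 1 (cocurvature, d ≥ 160 nm): 1/τ = b + A/d²,
* region 3 (plate deflection, d < 80 nm):
  1/τ = b + A·ρ²/(1 + 4r0²/d²)³, ρ = c/d.

η = τ/(τ + τ_trap) with τ_trap = 100 ps default.

## 5. Three-regime fitting

Rates (1/τ), not lifetimes, are fitted — variances are propagated from
the lifetime uncertainties by the delta method, and weighted fits are
invariant to a uniform rescaling of the stated uncertainties.  Records
labelled `LH2-L` (liposome overlays) are carried but excluded from fits
by default.

* Region 1: non-negativity-bounded weighted linear least squares on
  [1, d⁻²] (column-scaled; the unconstrained solution is used when it is
  already feasible, so noise-free data is recovered exactly).
* Region 2: weighted mean with a WLS slope-versus-size test (slope,
  standard error, p-value) so "plateau" is a checkable claim; single
  test, no multiplicity correction.
* Region 3: bounded nonlinear least squares with a deterministic
  multistart grid (3 amplitude scales × 3 charge coefficients × 2
  baselines).  Amplitude and charge coefficient are only jointly
  identifiable; the product A·c² is reported as the identifiable
  quantity.

**Boundaries.**  Fixed at 160/80 nm by default (the empirically
observed regime boundaries).  The opt-in
scan minimizes total weighted RSS over deterministic grids
(120…200 × 60…100 nm), with one subtlety: both outer-region laws nest a
constant, so shrinking the plateau can only lower the RSS by letting the
extra parameters absorb noise (and noise-free continuous data ties at
zero RSS for every d_high ≤ 160).  Partitions within
`rss_tolerance = 0.5` of the minimum — measured in units of the
minimum's per-point variance scale, so noise-free data admits no ties —
are therefore resolved parsimoniously in favour of the widest plateau.
The tolerance was fixed once on a 20-seed calibration of the synthetic
generator (median recovered boundaries exactly (160, 80)).

## 6. Synthetic data

The generator emulates the lifetime-versus-size measurement tables:
log-spaced diameters over 15–550 nm (8 per decade by default, n
configurable), a three-regime truth model, multiplicative Gaussian
lifetime noise τ → τ(1 + CV·z) (CV = 5 % default, factor floored at 0.1
to keep lifetimes positive under extreme draws), stated uncertainties
CV·τ, and a diameter-dispersion column (10 % default).  Truth defaults:
baseline rate 1/1.3 ns⁻¹ (the free-LH2 anchor), plateau 1/0.9 ns⁻¹,
boundaries 160/80 nm, r0 = 3.8 nm; the regime amplitudes are derived for
continuity at both boundaries, or — in the discontinuous mode that
mimics the observed sudden rate drop below ~80 nm — the region-3 branch
restarts at 75 % of the plateau.  All generators are pure functions of
(config, seed).

What the generator does *not* emulate: correlated errors between
neighbouring sizes, size-dependent noise floors, diameter measurement
error feeding into the fit (diameters are recorded at nominal values),
and any instrument response.  Passing recovery tests therefore
demonstrate estimator correctness under the stated noise model, not
robustness to those real-data effects.

A note on attainable recovery accuracy: with 40 log-spaced sizes, 14
fall in region 1, and at 5 % rate noise the weighted-least-squares
information bound for the region-1 amplitude is a ~14.5 % relative
standard error (≈10 % expected median absolute error) — the region-1
amplitude is the least identifiable truth parameter of the harness.  The
plateau, by contrast, is recovered to ~2.5 % with honest 95 % interval
coverage.

## 7. Known limitations

* No B800 ring, carotenoids, vibronic coupling, exciton dynamics or
  thermal weighting of states; "lowest state" is the lowest eigenvalue
  per realization.
* Point-dipole couplings (no transition densities); couplings beyond
  second neighbours are neglected.
* The plate model is a linear Kirchhoff plate with an idealized center
  support; no membrane elasticity or electrostatic double layer.
* Forces and charges are in model units; absolute deflection amplitudes
  in the small-particle regime enter through a single fitted prefactor.
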