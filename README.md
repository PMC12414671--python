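# lh2bend

Curvature-induced deformation of the LH2 B850 pigment ring and its
excitonic lifetime signature.

## The problem

The peripheral light-harvesting complex LH2 of purple photosynthetic
bacteria carries an 18-pigment bacteriochlorophyll *a* ring (B850) whose
lowest Frenkel-exciton state is optically dark on the ideal circular
geometry — an energy-storage design.  When LH2 sits on a curved, charged
surface (an intracytoplasmic-membrane vesicle, or a silica nanoparticle
standing in for one), the ring deforms: in-plane elliptically and
out-of-plane by bending.  Deformation brightens the lowest state,
shortens the B850 excited-state lifetime τ, and lowers the efficiency of
energy transfer to the reaction center, η = k_trap / (k_trap + k_decay) =
τ / (τ + τ_trap).

`lh2bend` implements the full quantitative chain from particle size to
lifetime, for people modelling pigment-ring photophysics or analysing
lifetime-versus-size measurements:

1. **Geometry** — parametric (or PDB-derived) B850 ring; elliptical
   deformation δr/r0, length-preserving mapping onto a sphere of diameter
   d, and Kirchhoff plate deflection profiles.
2. **Mechanics** — the critical circularization diameter
   d_c = a₀·[((b₀/a₀)^{2/3} − (b₀/a₀)²)/(1 − (b₀/a₀)^{2/3})]^{1/2},
   the cocurvature deflection Δz ≈ r₀²/2d, the axisymmetric biharmonic
   plate solution D∇⁴w = 0 under rim shear, and the curvature-dependent
   surface charge ρ = c/d.
3. **Excitons** — the 18-site Hamiltonian
   H = Σₙ Eₙ|n⟩⟨n| + Σₙ Σ_{m=1,2} t_{n,n+m}(|n⟩⟨n+m| + h.c.),
   Gaussian diagonal disorder of width Γ, and disorder-averaged
   oscillator-strength components f_z, f_xy of the lowest state
   (f_z ∝ Δz²; f_xy linear in δr/r0).
4. **Lifetime link** — f ∝ k_r + k_nr = 1/τ, with the size-scaling laws
   1/τ = b + A/d² (large d) and 1/τ = b + A·ρ²/(1 + 4r₀²/d²)³ (small d).
5. **Fitting** — a statsmodels-style `LifetimeSizeModel` that segments a
   lifetime-versus-size table into the three regimes (boundaries 160 and
   80 nm by default), fits each, tests the plateau, and optionally
   re-estimates the boundaries by a deterministic scan.
6. **Synthetic data** — a generator emulating the measurement tables
   (three-regime truth model, log-spaced 15–550 nm sizes, multiplicative
   lifetime noise), liposome overlay records, and PDB fixtures.

## Worked example

```python
import numpy as np
import lh2bend as lb

# mechanics: when does a charged sphere re-circularize the elliptical plate?
dc = lb.critical_diameter(lb.EllipseSpec(a0=11.0, b0=8.5))
print(f"critical diameter dc = {dc:.1f} nm")

# efficiency cost of a shortened lifetime
eta = lb.eet_efficiency(lb.EfficiencyParams(tau=1.3, tau_trap=0.1))
print(f"native EET efficiency = {eta:.3f}")

# exciton response to bending: <fz> of the lowest state vs deflection
dis = lb.DisorderModel(gamma=125.0, n_realizations=1000, seed=1)
sweep = lb.bending_sweep(np.geomspace(54, 550, 8), epsilon=0.057, disorder=dis)
slope = np.polyfit(np.log(sweep.delta_z_nm), np.log(sweep.mean_fz), 1)[0]
print(f"log-log slope of <fz> vs delta_z = {slope:.3f}")

# fit a (here synthetic) lifetime-vs-size table with the three-regime model
table = lb.generate_lifetime_table(lb.SyntheticConfig(n_sizes=40, seed=1))
res = lb.LifetimeSizeModel(table).fit()
print(res.summary())
```

prints

```
critical diameter dc = 13.7 nm
native EET efficiency = 0.929
log-log slope of <fz> vs delta_z = 2.002
Three-regime decay-rate fit (1/tau vs particle size)
========================================================
observations: 40   boundaries: d_high = 160 nm, d_low = 80 nm
--------------------------------------------------------
region 1 (d >= 160 nm): 1/tau = b + A/d^2
  A = 8587.17 +/- 1.4e+03 ns^-1 nm^2
  b = 0.763215 +/- 0.021 ns^-1   (n = 14, RSS = 13.7)
--------------------------------------------------------
region 2 (80-160 nm): plateau
  rate = 1.12869 +/- 0.021 ns^-1   (n = 7, RSS = 13.1)
  slope test: 0.00184 +/- 0.0015 ns^-1/nm, p = 0.265
--------------------------------------------------------
region 3 (d < 80 nm): 1/tau = b + A rho^2/(1+4 r0^2/d^2)^3, rho = c/d
  A c^2 = 2194.96 ns^-1 nm^2 (identifiable product)
  b = 0.794836 ns^-1   (n = 19, RSS = 5.76, starts = 18)
========================================================
```

The 13.7 nm critical diameter means any particle larger than ~14 nm
restores the ring's circular symmetry; the slope 2.00 is the quadratic
brightening law f_z ∝ Δz²; the fit recovers the generator's truth
(amplitude 8752 ns⁻¹nm², plateau 1/0.9 ≈ 1.111 ns⁻¹) within the quoted
uncertainties.  Region 3 reports the identifiable product A·c² because
amplitude and charge coefficient enter the rate only through it.

A command-line interface mirrors the stages:

```bash
lh2bend mechanics                # dc and deflections
lh2bend efficiency --tau-ns 0.7  # eta for a deformed complex
lh2bend synth --seed 1 --out table.csv
lh2bend fit table.csv --scan-boundaries
lh2bend pipeline --config run.yaml
```

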