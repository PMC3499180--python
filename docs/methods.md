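# Methods

## Scope and model

`growthplate` simulates longitudinal growth of the physis as the coupled
outcome of two columnar cell processes — proliferation and hypertrophy —
under sustained axial load. The model is deliberately minimal:

* **Growth law.** In equilibrium each proliferated chondrocyte completes
  maturation, so the growth rate is `G = n_p · h_max`. The continuum sees
  growth as a rank-one strain-rate tensor `ε̇ = d_prolif + d_hyper` along
  the growth direction `n` (+y). The proliferative contribution is
  `n_p h_p / l_p`; the hypertrophic one sums, over the cells of a column,
  the mean elongation rate `(h_i − h_p)/Δt_i` of each cell and divides by
  the zone width `l_h`. With cells seeded on the linear maturation ramp at
  ages `i·Δt` and `t_E = N_h·Δt`, the two contributions recombine exactly:
  `l_p·ε̇_p + l_h·ε̇_h = n_p·h_max = G` (asserted to 1e-10 relative in the
  tests — the master consistency identity of the kinetics).
* **Mechanical modulation.** Sustained load changes the terminal
  hypertrophic height: `h_max = (1 + D(Δσ_n))·h_max_f` with `D` piecewise
  linear in the stress difference `Δσ_n = σ_n − σ_n_f`. The branches
  implemented are `D = 0.35|Δσ|` for tension, `+0.27|Δσ|` for mild
  compression (to −0.1 MPa) and `−0.47|Δσ| + 0.074` beyond. Note the signs:
  they are forced by the calibration data (terminal heights 36.22, 35.00,
  35.94, 34.30 μm at +0.1, 0.0, −0.1, −0.2 MPa). A published form of this
  interpolation carries inconsistent signs on the compressive branches;
  this implementation treats the calibration heights as ground truth, which
  the tests pin to ±0.01 μm.
* **Elasticity.** Plane-strain, small-strain, linear isotropic elasticity
  on bilinear quadrilaterals with 2×2 Gauss quadrature, assembled sparse
  and solved by LU factorisation. Stress is recovered at element centroids
  (the superconvergent point for this element); the kinetics consumes the
  single number `σ_n = n·σ·n` per element. The elastic displacement field
  is *not* added to the growing geometry — under a sustained constant load,
  re-adding it every step would ratchet; growth is driven purely by `ε̇`.

## Domain, mesh and boundary conditions

The domain is an 800 μm square stacked bottom-to-top as metaphyseal
trabecular bone, hypertrophic, proliferative and reserve cartilage, and
epiphyseal trabecular bone; the two bone caps share the thickness the
cartilage leaves over (e.g. 180.85 μm each at baseline). Twenty chondrocyte
columns of 40 μm tile the width exactly. The structured mesh carries one
element row per chondrocyte in the columnar zones (so each element holds
one cell and the cell-distribution tensor per element is isotropic), one
element column per chondrocyte column laterally (configurable), and two
fixed rows in each non-growing region, which only transmit load.

Supports are a confined column: the bottom edge is fixed vertically, both
lateral edges ride on vertical rollers (`u_x = 0`), and a uniform traction
equal to the sustained stress is applied on the top edge (tension
positive). This choice is deliberate. The stacked layers differ enormously
in stiffness and Poisson ratio (bone E = 2000 MPa, ν = 0.30; cartilage
E ≈ 0.25–0.48 MPa, ν = 0.07–0.13); with free lateral edges the mismatch in
lateral contraction generates interface stress perturbations of up to
~19 % of the applied load in element-level `σ_n`, and the applied stress
would no longer be the stimulus the kinetics is calibrated against. Under
lateral confinement the exact solution is piecewise linear per layer,
bilinear elements reproduce it exactly, and `σ_n` equals the applied
traction in every element to ~1e-12 MPa, for any layer moduli. The
free-edge configuration remains available as an explicit
`BoundaryConditions` object and is exercised in the tests on a homogeneous
block, where the plane-strain uniaxial closed form `u_y = σ(1−ν²)H/E`
applies (the confined column obeys `u_y = σ(1+ν)(1−2ν)H/(E(1−ν))`).

Growth updates are Lagrangian: node rows inside a grown zone are stretched
uniformly and everything above translates; connectivity, column maps and
element-tissue maps never change, and updates are additive to 1e-9 μm.

## Parameters

| symbol | meaning | value / source |
| --- | --- | --- |
| `h_max_f` | terminal hypertrophic height, physiological | 35 μm |
| `σ_n_f` | physiological baseline stress | 0 MPa (loads are expressed as differences, so the applied traction *is* `Δσ_n`) |
| `l_r, l_p, l_h` | zone thicknesses per load case | fixture table (e.g. 12.3/264/162 μm at 0.0 MPa) |
| `N_p, N_h` | cells per column per load case | fixture table (e.g. 22 + 6 at 0.0 MPa) |
| `h_p` | proliferative cell height | `l_p / N_p` (columnar cells fill the zone; never reported directly, this is the only closure consistent with the thickness and census tables) |
| `t_E` | maturation time | `N_h · Δt` (one cell matures per turnover interval) |
| `n_p` | proliferation rate | `1/Δt` (equilibrium: one division per interval) |
| `Δt` | turnover interval | `h_max / G` per load case (0.158–0.209 days) |
| E, ν | tissue elasticity | bone 2000/0.30; reserve 0.48/0.07; proliferative 0.25/0.13; hypertrophic 0.27/0.13 MPa |

Units are μm, days and MPa throughout; forces carry MPa·μm per unit
out-of-plane thickness. Concentrations in the cell-distribution tensors are
optional bookkeeping (no numerical values are required by the growth laws);
anisotropic distributions (ratio ≠ 1) are explicitly unsupported because
only the one-cell-per-element isotropic case is ever exercised and the
general transversely isotropic form is not unambiguously documented.

## Time integration

Each full step spans one turnover interval `Δt`: elastic solve, per-column
growth-tensor evaluation from element-local `σ_n`, per-zone elongation
increments `ε̇_nn · l · Δt`, mesh stretch, then cell bookkeeping (all
hypertrophic ages advance by `Δt`, the oldest cell undergoes apoptosis, a
newly divided cell enters the hypertrophic column). The last step is
truncated so total time equals the requested duration exactly; a truncated
step integrates elongation but triggers no turnover event, since cell
division and apoptosis are whole events tied to full intervals — with
steady rates this leaves the integrated elongation unaffected (sub-interval
integration matches full steps to < 0.5 %).

By default the kinetic zone widths `l_p`, `l_h` and `Δt` stay at their
per-case setup values while the mesh itself elongates ("steady geometry"),
which matches the constant per-case turnover interval and steady rates of
the validation data. `steady_geometry=False` lets the kinetic widths track
the grown mesh; because the zone width cancels from the elongation
increment (`ε̇·l·Δt` is width-independent for both contributions), the two
modes produce the same elongation and differ only in the reported widths.

## Problem sizes and determinism

The validation runs use the default discretisation: 20 × 34–36 elements
(≈ 700 elements, ≈ 1 500 dof), 110–146 time steps over 23 days, a few
seconds per case on one CPU. There is no randomness anywhere in the model;
repeated runs produce byte-identical CSV output, and the acceptance script
ignores its seed beyond consuming it.

Because every cartilage element sees `σ_n` equal to the applied traction,
the simulated mean growth rate collapses to the closed form
`G = h_max(Δσ_n)/Δt` and matches the experimentally derived rates
(228.7, 217.0, 183.4, 163.8 μm/day) to numerical precision — well inside
the 3.73 % band the validation gate demands. Earlier published simulations
of the same configuration report rates a uniform ~3 % above that closed
form without describing the mechanism; no compensating factor is added
here, and agreement with those reported rates is tracked as a looser (5 %)
regression check.

## Limitations

* The biochemical regulation of the physis (PTHrP–Ihh loop, BMP/FGF) is
  assumed load-insensitive and is not simulated; extracellular-matrix
  synthesis and degradation are ignored as growth contributors.
* Only sustained (static) loading is modelled; dynamic/cyclic load effects
  are outside the model.
* The 2-D plane-strain domain omits the ring of Lacroix and other
  perichondrial structures, and the elastic description is linear and
  small-strain.
* Only the four experimentally characterised load cases carry measured
  zone thicknesses and cell censuses; intermediate stresses are served by
  opt-in piecewise-linear interpolation and should be treated as
  qualitative.
* Passing validation shows the implementation integrates its own growth
  laws consistently with the calibrated kinetics; it does not by itself
  validate the model against new experimental conditions.
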