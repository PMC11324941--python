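# Methods

This note documents the model, the numerical machinery, the choices
made where the design was genuinely open, and what the package's tests
do and do not establish.

## Physical model and assumptions

The scene is a 2D cross-section through an idealized cylindrical tumor:
a disk of radius `R_t = 5 mm` centered in a 25 mm x 20 mm rectangle of
healthy tissue, surrounded by a capillary annulus of thickness
`d_c = 0.25 mm` fed by two straight vessels of width `d_a = 1.5 mm`
reaching the lateral edges (inlet left at 2080 Pa, outlet right at
0 Pa gauge). A permanent magnet sits above the tissue on the vertical
symmetry axis; four shapes are studied (20x10 and 10x20 mm rectangles,
5 and 10 mm radius circles), all specified by a remanent flux density
(default 1.5 T) directed at the tissue.

Assumptions carried throughout:

* **Steady state, small strain.** The solid velocity vanishes; the
  coupling chain magnetics → vessel flow → tissue pressures →
  displacement is one-way, with no deformation feedback to the flow.
* **Plane strain** for the 2D elastic reduction (long-cylinder
  concept); the out-of-plane stress `σ_zz = λe − P_i − P_B` is kept in
  the von Mises invariant.
* **Linear magnetization, no saturation.** The blood–ferrofluid
  mixture has `μr_eff(φ) = 1 + 0.6 φ`, a linear mixing rule anchored so
  that `μr_eff(0.5) = 1.3` (the tabulated mixture value); plasma alone
  is non-magnetic. By default both the vessel blood *and* the tissue
  interstitium are treated as ferrofluid-bearing (the interstitial
  momentum balance carries an `ε_i F_mag` term); a blood-only mode is a
  switch (`magnetize_interstitium=False`).
* **Starling exchange** is linear in the pressures. Two scalars the
  study tables omit carry implementer defaults, clearly marked in
  `params.py`: lymph pressure `P_L = 0 Pa` and blood colloid osmotic
  pressure `π_B = 2666 Pa` (≈20 mmHg, a typical plasma value). The
  tumor has no lymphatic drainage.
* **Tabulated values at face value**, including an interstitial
  viscosity of 1.32 Pa·s that is physically large; everything is
  overridable via config.

## Pipeline and discretization

All solves use linear (P1) triangles assembled by the in-package FEM
core (`fem.py`) with sparse direct factorization. Three per-physics
meshes are generated programmatically (there is no external input
data — the geometry/mesh module is the synthetic-data generator):

* **Magnetics mesh**: air box (half-size ≥ 0.18 m, chosen because the
  `ψ = 0` truncation acts like a permeable wall and biases the interior
  field at the percent level for smaller boxes), magnet and tissue,
  with graded shells in the far field. Scalar-potential solve; `H`, `B`
  and `M` are recovered per element and patch-averaged to nodes; the
  Kelvin force `2 μ0 μr_eff χ_eff (H·∇)H` (the linear-media form of
  `(M·∇)B + (B·∇)M`) is evaluated anywhere by interpolating the
  recovered `H` and its recovered gradient.
* **Flow mesh**: a structured, exactly conforming mesh of the annulus
  plus feeders — the annulus is meshed in polar coordinates with its
  outer-circle nodes coinciding with the feeder end columns, at least
  two (default four) elements across the 0.25 mm channel. Stokes flow
  (the convective term is optional and off by default: with it on, the
  solve is Picard-linearized Navier–Stokes) with P1-P1 elements and
  Brezzi–Pitkäranta pressure stabilization (α = 0.05, h² = 2·area).
  The shear-thinning viscosity is resolved by Picard iteration with
  geometric under-relaxation (μ ← sqrt(μ_old·μ_target)), relative
  velocity-increment tolerance 1e-6; the shear rate is regularized to
  [1e-3, 1e5] s⁻¹ so μ_B stays finite at stagnation points.
* **Tissue mesh**: spiderweb rings inside and around the tumor (with
  node circles exactly on the tumor/ring interface radii) grading into
  a rectangular grid. The capillary band is tagged but behaves as
  healthy tissue in the porous problem; the vessel couples to the
  tissue through (a) Dirichlet data for `P_B` on the interface circle,
  interpolated from the flow solution's inner-wall pressure by angle,
  and (b) the shared `F_mag` field.

The tissue and magnetics meshes are built by triangulating the
half-plane x ≥ 0 of the (symmetrized) point cloud and mirroring it, so
a mirror-symmetric scene yields a bitwise mirror-symmetric mesh and
mirrored magnet placements yield identical meshes — this is what makes
the symmetry tests exact to solver round-off rather than to
discretization error.

The three tissue fields are solved sequentially (`P_B → P_i → u`);
because the steady problem is linear and the coupling triangular, this
equals the monolithic solution exactly. Dirichlet conditions are
imposed by elimination. Boundary conditions follow the stated roles:
rollers (`u·n = 0`) on the bottom, top and lateral edges; optional
boundary load on the top edge (default zero — note a purely normal
load there is absorbed by the roller constraint); no interstitial flow
through the bottom; `P_i = 0` on top and lateral edges; vessel
pressures at the feeder ends; no-slip vessel walls.

## Reduced-system residual oracle

Taking divergences of the momentum balances collapses the coupled
system to three scalar equations in (`e`, `P_i`, `P_B`) — with
`c = 2μ + λ`: `c∇e = ∇P_i + ∇P_B`, and its Laplacian combined with
continuity, plus `−∇²P_B + ∇·F_mag = 0`. The displacement-based solve
is verified against this reduced system by evaluating the weak
residuals of all three equations on the tumor disk against smooth
bump-polynomial test functions `(1 − (r/R_t)²)² · {1, x, y, xy, x²−y²}`
whose value *and* gradient vanish at the rim. Both derivatives are
moved onto the test functions, so the residual needs only raw field
values (element strains, nodal pressures) — no gradient recovery of
the discrete strain, whose reconstruction noise would otherwise
dominate. Each residual is normalized by the integral of the largest
term's |integrand|. A manufactured polynomial solution converges at
second order; residuals of actual solves shrink under refinement. The
oracle tests restrict to the tumor disk because the reduced equations
assume uniform coefficients and no source sheets, which holds there
even in the heterogeneous baseline.

## Mesh presets and problem sizes

Two presets balance resolution against runtime: `coarse`
(tissue h 0.4 mm, ~1.1 k tissue nodes; 4-layer vessel mesh; magnetics
h 0.8 mm, ~4 k nodes; <1 s/case) for property sweeps, and `default`
(tissue h 0.25 mm, ~2.2 k nodes; 5-layer vessel mesh; magnetics
h 0.5 mm, ~8 k nodes; ~2 s/case) for reported quantities. Profile
means use 201 evenly spaced samples; the "linear average" is the
arithmetic mean of the samples (a least-squares linear fit is available
behind `fit="least_squares"`).

## Findings the simulator's own studies establish

With the tabulated parameters the simulator reproduces the expected
qualitative physics: the tumor-interior flux density orders as
BC > HR > VR > SC; with the magnet on, the maximum vessel pressure
moves to the top of the capillary ring; mean tumor stress increases
strictly with remanence and ferrofluid fraction and decreases strictly
with magnet distance, with the largest drop on leaving tangential
contact.

One finding deserves emphasis because it is a genuine property of the
2D cross-section model: at tangential contact, integrated tumor stress
is *larger* for the vertically placed rectangle than for the
horizontally placed one, although the horizontal one produces the
larger field deep inside the tumor. In 2D, a narrow-faced magnet
concentrates flux — the closed-form field of a uniformly magnetized
strip shows the 10 mm-wide magnet exceeding the 20 mm-wide one at all
depths shallower than ≈7 mm below the face, which covers the capillary
ring and upper tumor that dominate the Kelvin-force loading. The
intuition that a larger contact surface means a larger effect holds for
flat 3D magnets but not in this 2D reduction. For the same reason the
big circle loads the tumor center strongly enough that its diameter
stress profile peaks centrally rather than at the rim.

## Limitations

* 2D cross-section only; no 3D or semi-realistic vasculature.
* The synthetic geometry idealizes the capillary bed as a single
  annulus with two feeders; real peritumoral networks are dense and
  irregular, so absolute pressures and stresses should be read as
  model-scale quantities, not tissue measurements.
* Linear elasticity at strains that reach a few percent near the ring
  under strong forcing; no growth-induced residual stress; no
  transient consolidation.
* No magnetization saturation or hysteresis; permanent magnet reduced
  to a uniform remanence.
* The vessel walls transmit pressure but do not deform; pulsatility and
  red-cell mechanics are out of scope.
* Blood-flow Reynolds numbers implied by the tabulated millimeter-scale
  vessel dimensions are not small; the Stokes default is a modeling
  choice (the convective mode is available) and wall pressures should
  be compared between cases rather than read as absolute predictions.
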