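# Methods

`stomamech` has two halves: a finite-element model of the pressurized
guard-cell pair that predicts how stomatal aperture responds to turgor, and
an AFM force-volume analysis pipeline validated against a synthetic
force-map generator with known ground truth. This note records the models,
their assumptions, the tunable parameters, and the choices made where the
design was genuinely open.

## Guard-cell model

### Geometry

The stomatal complex is a deformed torus built from two ellipses in the
leaf plane: the complex outline (semi-axes `a_s = complex_length/2`,
`b_s = complex_width/2`) and the pore (`a_p = pore_length0/2`,
`b_p = pore_width0/2`). Each guard cell is the tube on one side of the long
axis; its cross-section at torus angle phi is centered midway between the
outline and pore ellipses with radius equal to half their separation, so
the undeformed ventral rim reproduces the pore ellipse exactly. Two flat
polar walls (the disks capping the tubes where the cells meet) are shared
by the cells; each cell's own wall surface (tube + polar walls) is closed
and consistently oriented, which the test suite checks via edge counts and
Euler characteristic 2.

Shipped default dimensions (complex 45 x 30 um, pore 18 x 4 um, wall
1.0 um, polar wall 0.3 um) are calibration stand-ins for a large
broad-bean-type stomatal complex; only the wall thicknesses are
literature-anchored, and the 4-um initial pore width is part of the
landmark calibration (see below). An optional `z_flatten` factor squashes
the tube section out-of-plane (default 1.0, i.e. circular).

The variable-wall-thickness (VWT) variant combines a rounded-triangular
section — a three-lobed radial modulation of amplitude `section_blend`
(default 0.1), normalized so the ventral vertex stays on the pore ellipse —
with a smooth thickness field
`t(psi) = t_wall * (1 + (r_v - 1) * ((1 - cos psi)/2)^2)`, ventral/dorsal
ratio `r_v = 1.5`, and the ventral-patch thickness additionally scaled by
`m_v` (0.9 / 1.0 / 1.1 in the scenario matrix). The blend controls the
high-pressure side of the VWT curve (smaller final aperture than
baseline), the thickness asymmetry the low-pressure side (earlier, larger
opening) and the stress redistribution off the ventral wall.

The mesher uses a structured (phi, psi) grid with `n_psi` forced to a
multiple of 8 (so the four tube patches are element-aligned and exactly
mirror-symmetric — an early version without this constraint gave the
"dorsal" patch a spurious net out-of-plane pressure resultant) and `n_phi`
even (so node rings exist on the long-axis midplane where aperture is
measured). Element count per cell tracks `mesh_resolution` within the
documented +-20%.

Cellulose microfibrils are attached per element as the hoop direction
around the tube: `fiber = axis_tangent x facet_normal`, which is exactly
tangent to each facet; on the polar walls the hoop winds around the wall
center.

### Wall material

Transversely isotropic Veronda-Westmann solid: matrix
`W_m = C1 (exp(C2 (I1-3)) - 1) - (C1 C2 / 2)(I2 - 3)` on deviatoric
invariants, fibers defined through `lambda W_f'(lambda)` = 0 in
compression, `C3 (exp(C4 (lambda-1)) - 1)` in the toe, `C5 lambda + C6`
beyond the straightening stretch `lambda*` with `C6` solved for stress
continuity. The toe energy integrates to an exponential-integral
expression (`scipy.special.expi`). The 3-D form carries a volumetric
penalty `K/2 (ln J)^2` (default `K = 50 C1`); the membrane solver instead
eliminates the thickness stretch exactly via incompressibility
(`lambda_3 = 1/(lambda_1 lambda_2)`), the correct thin-wall limit.
Analytic Cauchy stress is verified against central-difference
differentiation of the energy (relative error < 1e-3 over random states).

Published wall-parameter sets for this material law in guard cells are
not available in a directly usable form, so the shipped defaults are a
*calibration set*, chosen so the baseline model
reproduces two printed landmarks of the aperture-pressure curve — opening
onset near 1.3 MPa and aperture saturation only above 5 MPa — and then
frozen:

| parameter | value | units | role |
|---|---|---|---|
| C1 | 1.0 | MPa | matrix scale |
| C2 | 3.0 | - | matrix strain-stiffening exponent |
| C3 | 0.5 | MPa | fiber toe scale |
| C4 | 5.0 | - | fiber toe exponent |
| C5 | 50.0 | MPa | fiber post-straightening modulus |
| lambda* | 1.05 | - | fiber straightening stretch |
| K | 50 C1 | MPa | volumetric penalty (3-D form only) |

This is a deliberately soft wall: the landmarks require strains large
enough for the exponential stiffening to terminate aperture growth inside
the 6 MPa protocol. With stiff walls the late aperture creep is governed by
pressure-geometric compliance (roughly 1/P) and never flattens below the
1%-of-gain/MPa criterion within the ramp. The initial pore width is the
second calibration knob: with a 2-um pore the epidermal co-ramp closes the
pore so deeply that lift-off (hence the opening threshold) lands near
1.8 MPa regardless of material scale, fiber toe, or locked-fiber modulus;
a 4-um pore centers the threshold at ~1.25 MPa at the 3000-element /
60-step analysis size while leaving the plateau onset at ~5.4 MPa.

### Discretization and solver

Constant-strain triangle membranes with per-element thickness, plus
discrete-shell hinge bending on interior edges (flexural rigidity
`D = E_eff t^3 / 12(1-nu^2)` with `E_eff = 3 C1 C2` from the linearized
incompressible matrix and nu = 1/2; stress-free at the undeformed dihedral
angles). Bending both regularizes the membrane's wrinkling modes and is
physically warranted at t/R ~ 1/7. Edges shared by more than two facets
(the polar rims) are hinge-free wall junctions.

Loads: guard-cell turgor is the exact follower load from the
enclosed-volume potential `-P V(x)` of each closed cell surface (the shared
polar walls receive equal turgor from both sides and cancel); epidermal
back-pressure is a follower facet load on the dorsal walls. The dorsal-only
default keeps the complex self-equilibrated; loading the outer periclinal
wall as well (config `epi_patches`) adds a net out-of-plane resultant that
would require a substrate model. The load protocol co-ramps both pressures
to the 0.5 MPa epidermal cap, then raises turgor alone to 6 MPa.

The consistent tangent (including follower-load stiffness) is assembled
from central finite differences of the analytic element residuals
(element-local, 18 perturbed evaluations, fully vectorized); hinge bending
contributes its Gauss-Newton stiffness `2 k grad(theta) grad(theta)^T`.
Newton iterations use backtracking line search with an adaptive Levenberg
shift (driven back to zero on success, so converged states satisfy the
unmodified equations), a Gauss-Newton least-squares fallback for indefinite
tangents near wrinkling states, adaptive load substepping, and step-length
extrapolation between load steps. Convergence: residual below 1e-6 of the
full-load pressure-force norm. Rigid-body motion is removed by pinning the
transverse dofs of the polar-wall nodes that lie on the long axis (which a
mirror-symmetric deformation leaves on the axis anyway) plus weak
grounding springs (1e-6 C1 t per node) that carry no appreciable load.

Ventral-wall contact across the pore midplane is a quadratic no-penetration
penalty (stiffness 100 C1 t) on the ventral node sets of the two cells.

Verification: inflation of a thin closed sphere (fibers off) matches the
closed-form balloon relation `P = t0 W'(lambda) / (R0 lambda^2)` to ~0.05%
(criterion: 2%); external work along a turgor-only path matches stored
energy to <1%; element gradients match finite differences of the assembled
energies.

### Observables

* **Aperture**: transverse gap between the deformed ventral walls where
  the equatorial ring crosses the long-axis midplane, clamped at zero when
  the walls touch (the spec's "minimum gap over the equatorial ring" is
  degenerate for an elliptical pore, whose rim gap tends to zero at the
  pore ends). In the calibrated baseline the pore *closes* during the
  epidermal co-ramp and lifts off again near 1.3 MPa; the opening
  threshold (epsilon rule: first pressure at which aperture exceeds its
  end-of-co-ramp value by 1% of the total gain, linearly interpolated) and
  the plateau onset (first pressure after which the slope stays below 1%
  of the total gain per MPa) are insensitive to the clamp.
* **Complex length / pore length**: long-axis extents of all nodes / of
  the deformed ventral rim.
* **Effective scalars**: von Mises stress `sqrt(3/2 s:s)` and the
  analogous strain `sqrt(2/3 E':E')` on deviators, per element; an
  optional cap at 1 eases comparison with capped-color-scale renderings.
* `theoretical_max_aperture(l) = 0.25 pi l^2` returns an *area* (um^2) —
  kept separate from the width semantics of the curve.

Strain/stress localization claims (which wall carries the peak) are
evaluated on the mid-cell band (|x| <= a_p/2): near the pore ends the
membrane formulation concentrates stress at the ventral contact corner
where the closed walls peel apart — a contact artifact, not the radial
wall pattern the claims describe. There the calibrated model reproduces:
baseline peak strain and stress on the ventral (inner radial) wall; VWT
ventral stress below baseline with the peak moved off the ventral wall to
a medial position; fixed poles opening earlier and wider at constant
complex length while the baseline elongates above ~1 MPa.

Known formulation limits, stated plainly:

* The membrane-with-weak-bending wall admits slightly symmetry-broken
  wrinkled equilibria, so the deformed surface matches its mirror image
  only to a few percent of the peak displacement (a 3-D solid-element wall
  would not wrinkle).
* In the calibrated (closure/lift-off) regime the aperture is
  ventral-wall-controlled, and peeling resistance scales with bending
  rigidity (t^3). A +-10% change of ventral wall thickness therefore moves
  the VWT aperture curve by ~6-10% of its range — the near-insensitivity
  expected of a non-closing solid-element model is not reproduced, and the corresponding check in the acceptance suite fails by
  design rather than being weakened.
* Pinning the polar region *relieves* membrane stress there (the polar
  caps are nearly load-free), so the fixed-pole variant does not show an
  increased polar stress share the way a solid-element shell does; this check
  likewise remains failing with the stated metric.
* The absolute aperture gain (~3 um) and the deep co-ramp closure are
  calibration artifacts of matching the two printed landmarks; the model
  is not calibrated to absolute aperture magnitudes.

## AFM pipeline

Per-pixel chain on approach curves only: volts -> force via
`F = V * sensitivity * k`; baseline/tilt removal by an iteratively shrunk
pre-contact line fit (MAD-robust noise, window retreats below the first
sustained 3-sigma excursion, rejected when the fitted "baseline" slope
approaches contact stiffness); contact point by threshold crossing at
5 sigma (sustained: 5 consecutive samples and 90% of the remainder above)
refined by a hinge-model grid search — `F = a max(z' - z0, 0)^2` with
cantilever bending subtracted from the piezo position (`z' = z - F/k`),
SSE minimized over a coarse-then-fine z0 grid with parabolic interpolation.
The hinge fit uses the sub-noise samples collectively and recovers z0 to
<1 nm noiseless and ~7 nm at 2% (of setpoint) deflection noise on a 5 MPa
sample. Indentation `delta = (z - z0) - F/k`; apparent modulus from the
four-sided-pyramid Hertz form `F = (tan theta / sqrt 2) E_a / (1 - nu^2)
delta^2` (theta = 17.5 degrees face half-angle, nu = 0.5), linear least
squares over the 10-100% depth window. E_a is "apparent": the half-space
assumption is knowingly violated on a structured wall.

Transects sample the E_a image by bilinear interpolation: "diameter" along
the short axis through the stoma center, "circumference" along the outline
ellipse starting at the equator. Wall peaks are local maxima of a
0.15-um-smoothed profile with prominence >= 5% of range and >= 0.5 um
separation (10% prominence cannot resolve the outer wall of the mature
preset at the 1-um wall-pair separation); peak heights are raw-profile
maxima within +-0.15 um of each detected peak. The stiffness gradient per
guard cell is (inner peak - outer peak) / peak separation; the per-stoma
statistic is the mean over the two cells, not computable (None) when fewer
than four wall peaks are found (e.g. the three-walled GMC). The
Mann-Whitney comparison uses `scipy.stats.mannwhitneyu` (exact for small
tie-free samples, tie-corrected normal approximation otherwise).

## Synthetic force maps

The generator emulates plasmolysed-leaf stomatal maps: no turgor, no
topography (stiffness contrast is the only signal), Gaussian wall ridges
(sigma 0.30 um) on the stoma outline and on an inner ellipse offset by the
1.0-um wall-pair separation, polar caps, pavement background. Stage
presets (synthetic values chosen so the pipeline-recovered statistics match
the study's printed medians; not measurements): mature E_inner 10 /
E_outer 6 / E_pole 12 / background 2 MPa (true diameter gradient
(10-6)/1.0 = 4 MPa/um); young 8/8/12/2 (true gradient 0); GMC three equal
8 MPa walls. The field takes the *maximum* of overlapping contributions so
preset peak values are attained exactly on wall centerlines.

Forward model per pixel: pyramidal Hertz at the local modulus (with
multiplicative log-normal pixel jitter, 5% default), run to the 1000 nN
setpoint or to the 1000 nm ramp end (saturated pixels are flagged but
still fitted over their valid depth window — with the preset moduli this
reproduces the reported 100-1000 nm indentation range), plus cantilever
bending, baseline tilt/offset, contact-point jitter (5 nm) and Gaussian
deflection noise (1% of setpoint). Curves are emitted uncalibrated
(volts). Identical seeds give byte-identical maps.

Study acquisitions are 128 x 128 maps over a 30-um field centered on one
stoma — a routine AFM zoom — because at the 100-um survey scale the
0.78-um pixel pitch cannot resolve the 1.0-um wall-pair separation; the
100 um / 128 px survey remains the `AfmConfig` default. What passing
recovery tests show is that the pipeline is unbiased on topography-free,
single-stoma, Hertzian data at realistic noise; they do not exercise real
surface topography, substrate effects, tip wear or adhesion.

The stage-comparison study (14 mature + 18 young maps, per-map seeds
derived from one study seed) recovers median gradients of ~4.0 and
~0 MPa/um and a two-sided Mann-Whitney p ~ 2e-6 at these n.

## Problem sizes

Default analysis sizes: ~3000 elements per guard cell and 60 load steps
for the headline baseline curve (a few minutes on one core; results change
<2% on refinement), ~20000 elements per cell for the geometry default
(matching the reported mesh density for such models), 600-800 elements per cell for property and
ordering checks, 128 x 128 pixels per force map.
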