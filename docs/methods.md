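# Methods

## The question the simulations answer

Cardiac-region electrical impedance tomography (EIT) suffers from low
central sensitivity: with a ring of skin electrodes, the resolution is best
at the periphery and worst at the centre, and the high-impedance lungs
flanking the heart make it worse.  An electrode carried on an oesophageal
catheter sits directly behind the heart and should restore central
sensitivity.  This package quantifies that idea entirely in silico: it
simulates a cylindrical thorax phantom under two electrode layouts — all 16
electrodes on the outer wall ("external"), versus electrodes 1–15 on the
wall and electrode 16 on the wall of an axial oesophageal channel
("internal") — and scores how well each layout reconstructs a small blood
conductivity perturbation at radial positions between the centre and the
wall.

## Phantom

A cylinder of diameter 2 and height 0.8 (model units; the geometry of a
laboratory saline tank, everything scales with it).  Materials at 50 kHz,
entered as real conductivities: background chest tissue 0.48 S/m, inflated
lung 0.13 S/m, blood 0.7 S/m.  Two full-height lung cylinders (diameter
0.8) sit at (±0.55, 0); the blood target is a full-height cylinder
(diameter 0.1 by default) moved along the −y axis toward electrode 9, so
its corridor never crosses the lungs.  Electrode ℓ (1-based) is a disc of
diameter 0.1 centred at angle 2π(ℓ−1)/16 from +y at height z = 0.4.  In the
internal arrangement the axial channel (diameter 0.1, full height) is
meshed out as a void — the catheter body is not conductive tissue — and
electrode 16 becomes a ring band around the channel wall whose height
(0.025) gives it exactly the area of the external discs, the shape of a
catheter ring electrode.  Contact impedance is 10⁻³ Ω·m² on every
electrode (the value is not critical; it is identical across electrodes so
that arrangement comparisons are not confounded).

### Meshing

No general tetrahedral mesher is bundled; the phantom's cross-section ×
extrusion structure is exploited instead.  A 2-D Delaunay triangulation of
a structured point cloud (graded boundary ring with refinement under the
electrode bands, explicit node rings on every material-interface circle, a
jittered hexagonal background lattice) is extruded through a graded stack
of z-layers (refined across the electrode band, with exact layers at the
electrode and ring-band edges) and every prism is cut into three
tetrahedra with diagonals chosen from global vertex indices, which makes
the cut agree across shared faces — the mesh is conforming by
construction and the invariant is asserted in the tests.  Region labels
come from the parent 2-D triangle against the feature circles, so material
interfaces are polygonal chords of the exact circles (16-gon or finer:
≤ 1.3 % area error).

Two evaluation-grade densities are built from incommensurate size factors
and different jitter streams: the *forward* mesh (≈ 35 000–42 000 elements)
simulates the data and the *inverse* mesh (≈ 29 000–34 000 elements)
carries the reconstruction, so the inverse problem never sees the
discretization that generated its data.  All randomness in meshing flows
through a seed; a spec plus seed reproduces the mesh byte-for-byte.
Uniform (red) refinement — each tet into eight nested children — provides
the convergence oracle: the evaluation-grade frame changes by 1.6 % when
the mesh is refined once, and successive refinements shrink the change.

## Forward model

The complete electrode model: ∇·σ∇u = 0 inside, u + z_c σ ∂u/∂n = U_ℓ
under electrode ℓ with the patch current integrating to I_ℓ, zero normal
current elsewhere.  First-order tetrahedral elements give the standard
symmetric augmented system in vertex potentials and electrode voltages,
factorised once per conductivity state (sparse LU) and reused for all 16
injections.  Uniqueness needs charge conservation (pair drive gives it
exactly) and a gauge: the default enforces ΣU_ℓ = 0 through a rank-one
augmentation of the electrode block that leaves the physical solution
untouched; a grounded-node option pins the potential at the bottom-centre
vertex (the tank's ground electrode).  Difference frames are
gauge-invariant, which the tests assert, so the study results do not
depend on this choice.

Stimulation follows the adjacent protocol at 1 mA: drive pairs (ℓ, ℓ+1),
measurements on every adjacent pair not touching a drive electrode —
16 × 13 = 208 voltages per frame.  The internal arrangement keeps
index-based adjacency, so electrode 16 still drives with 15 and 1 and is
measured against its index neighbours; this produces the amplified
channels involving electrode 16 that the voltage-trace experiment shows.

### Noise

Measurement noise is additive white Gaussian, std = 0.05 % of the
root-mean-square voltage of the reference frame, identical on every
channel, applied independently to the reference and target frames.
Reading the quoted noise level against the rms (typical) voltage keeps the
noise white (C_n ∝ I, so the unweighted residual is already whitened) and
carries the same noise energy as reading it per channel; reading it
against the frame *maximum* instead would put the deep D = 0.1 target's
entire difference signal (≈ 0.4 × noise) under the noise floor and no
reconstruction would resolve it, which is inconsistent with the
well-resolved images this noise level is known to permit.  Both
arrangements receive the same standard-normal draws for a given experiment
cell (common random numbers), scaled by their own frame rms — a paired
design that sharpens the arrangement comparison without changing either
marginal result.

## Inverse model

One-step linearised difference imaging.  The sensitivity matrix J
(208 × n_elements, volts per S/m) is assembled by the adjoint-field
identity −I·∫ₖ ∇u_d·∇u_m dV from 16 unit-current fields on the inverse
mesh at the lungs-plus-background reference conductivity; a central
finite-difference oracle checks sampled entries to < 10⁻³ relative.  Note
J has numerical rank ≈ 104: reciprocity makes half of the 208 adjacent
measurements redundant.

The estimate minimises ‖ΔV − J δσ‖² + λ²‖L δσ‖².  The default weighting is
L = diag(‖J column‖) (NOSER), i.e. prior covariance C_δσ⁻¹ = diag(JᵀJ): a
plain identity prior concentrates the reconstructed change in the
high-sensitivity shell next to the electrodes and systematically
under-recovers deep targets — under it the internal arrangement never
beats the external one anywhere, for any λ, contrary to the physics the
study design is meant to expose — while the sensitivity-weighted prior
equalises amplitude response over depth and is the standard one-step
difference-imaging prior in EIDORS-based work.  Identity and general
operators remain available; identity priors are what the dense-oracle
tests exercise.  For identity/diagonal operators the solution is evaluated
exactly through the thin SVD of the whitened operator (cached), making the
λ scan essentially free; general matrix operators fall back to an
iterative stacked least-squares solve.

### Choosing λ: the L-curve corner

λ is scanned on a log grid and the corner — the point of maximum curvature
of the (log residual, log seminorm) polyline — is selected automatically.
Curvature is computed geometrically: path points closer than a small
fraction of the total arc length are collapsed first (at both grid ends
the curve barely moves and finite differences there manufacture spurious
curvature), then the Menger circumcircle curvature is evaluated on
surviving triples, keeping only bends that turn the way an L-corner does.
Degenerate data (zero, or consistent to machine precision, or no positive
curvature anywhere) return the smallest grid λ by convention.  A dense-SVD
curvature oracle on a classic ill-posed smoothing-kernel toy pins the
detected corner to within one grid step.

Reported λ values are normalised by the largest singular value of the
whitened sensitivity operator, which makes them comparable across
arrangements and mesh densities; the absolute value is also recorded.  The
pipeline scans 180 points across λ/s_max ∈ [10⁻⁸, 1]: a 40-point grid's
spacing (× 1.5 per step) is coarser than the corner separation between the
two arrangements, and the corner of the whitened problem sits near
λ/s_max ≈ 0.1–0.3, so a narrower span would clamp both arrangements to
the same boundary point.  The library default for a bare `lcurve_scan`
remains 40 points over [10⁻⁸, 10⁻¹].

## Scoring

Reconstructions are point-sampled onto a 64 × 64 raster across the
electrode plane z = 0.4 (pixel centres outside the mesh — outside the
boundary circle, or in the channel — are masked, never extrapolated) and
thresholded at one quarter of the peak amplitude in the peak's sign
direction.  Against the known target footprint the report contains:

* **AR** — summed quarter-set amplitude over summed true contrast on the
  true target pixels (1 = perfect recovery);
* **PE** — distance from the amplitude-weighted centre of gravity of the
  quarter set to the true centre (model units);
* **RES** — quarter-set pixels as a fraction of all in-boundary pixels;
* **SD** — quarter-set area outside the true target over the true target
  area;
* **RNG** — opposite-sign amplitude in the annulus of twice the
  quarter-set's equivalent radius, relative to in-set amplitude.

## Experiments

All experiments share one recipe (forward phantom with the target meshed
in; reference = same mesh, target at background, because ventilation is
held and only blood moves; noisy frames; difference; corner
reconstruction on the target-free inverse mesh; raster scoring):

1. **Voltage traces** — a blood cylinder of radius 0.30 at offset 0.5
   grows to 0.35 (heart-sized volume change); 208-sample ΔV traces for
   both arrangements.  This perturbation is large enough to brush the
   lungs, so the trace experiment runs without lungs, as a pure
   perturbation-response measurement.
2. **Comparison table** — D = 0.1 target at offset 0.5 (the cardiac
   position, furthest from every electrode), both arrangements, all five
   metrics plus the corner λ.
3. **Position sweep** — the same target at offsets 0.2 … 0.8 in 0.1
   steps.
4. **Deep-target pair** — D = 0.2 target at offsets 0.2 and 0.8; the
   headline number is the internal/external peak-image-intensity ratio at
   0.8.

Determinism: every stochastic step (mesh jitter, noise) derives from the
run seed; re-running a configuration reproduces the output CSVs
byte-for-byte.

## What the phantom does and does not emulate

It captures the geometry-driven physics the comparison turns on: finite
electrodes with contact impedance, the lung shadow, depth-dependent
sensitivity, measurement noise, and the inverse-crime guard.  It does not
model realistic thorax boundary shapes, breathing or cardiac motion of
the electrodes, oesophagus wall tissue, multi-frequency admittivity, or
hardware artefacts; conclusions about those require the tank and animal
experiments this model abstracts.  Metric values therefore transfer to
real data only as orderings and trends, not as absolute numbers.

## Numerical and design choices, in brief

* First-order elements; per-state sparse LU; solutions reused across
  injections.  Reciprocity holds to ~10⁻¹⁵, asserted at 10⁻⁸.
* Electrode patches are facet sets: external discs by geodesic distance on
  the unwrapped wall (area within a few % of πr² at evaluation densities,
  asserted within 20 %); the internal ring band is exact by construction.
* Element regions by centroid test; conductivity painting recomputes the
  geometric test rather than trusting stored labels.
* σ → aσ alone does not scale voltages by 1/a under the complete
  electrode model (the z_c term breaks it, ~1.5 % at default values); the
  exact invariance (σ → aσ, z_c → z_c/a) ⇒ V → V/a is what the tests
  assert.  Similarly a tenfold z_c change moves far-field channels by
  ~1–4 % depending on mesh density — small, but not below 1 %.
* The λ grid, corner convention and λ normalisation are as above; Table-1
  style λ values from other toolchains fix the scale only loosely, since
  neither the grid nor the corner detector nor the Jacobian scaling
  convention transfers between implementations.

## Known limitations

* At 0.05 % rms noise the deep D = 0.1 target has signal-to-noise near 1;
  single-frame metrics at offset 0.5 carry noticeable seed-to-seed spread
  (the paired noise design controls the *comparison*, not the marginals).
* The quarter-amplitude set on a 64 × 64 raster quantises RES and SD for
  an 8-pixel target; SD in particular is dominated by blur spill and sits
  well above published values computed under unrecoverable conventions,
  while every published *ordering* reproduces.
* The one-step linearised reconstruction is biased for the 46 % blood
  contrast (total recovered Σδσ·volume is within a factor of ~3, asserted
  for a small-contrast target); iterative Gauss–Newton is out of scope.
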