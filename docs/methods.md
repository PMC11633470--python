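# Methods

This note records the models, numerical choices and limitations behind
`welltfm`, in the order the pipeline runs.

## Geometry and conventions

The gel is a square prism (side `lateral_extent`, height `gel_height`)
bonded to glass at its base, with a cylindrical cavity of radius R and
depth d opening on the top face; the cavity rims are rounded by fillets
(defaults 0.5 µm at the bottom edge, 1.0 µm at the top).  Coordinates are
right-handed with z increasing from the glass toward the objective; θ is
counter-clockwise from +x; all lengths are µm.  Internally forces are pN
and tractions Pa (1 Pa·µm² = 1 pN), which keeps matrix entries near unity.

Surface localization follows the bead channel: the gel top is the plane of
maximum plane-mean intensity (beads accumulate at free surfaces), the well
bottom is the top minus the model depth (a standard-deviation-based bottom
detector was deliberately not implemented — the intensity statistic is too
erratic there), and the wall is a cylinder through the detected
circumference.  Circle detection uses a disk matched filter for the center
plus a radial edge-gradient circle fit, with an analytic curvature
correction (≈σ²/2R) for the smoothing-induced inward bias of the edge;
noiseless disks of radius 5–10 µm are recovered to ≲0.03 µm.  A manual
circle always bypasses detection.

## Synthetic data

`synthetic` is a first-class forward model, not a fixture dump.  Bead
counts are Poisson with mean density × region measure: a uniform bulk
(default 0.23 µm⁻³ ≡ 0.0005 beads/voxel, the density above which
volumetric PIV error saturates) plus surface layers on the gel top, well
wall and well bottom (default 1.1 µm⁻², ≈12 beads per interrogation box at
a surface).  Layer depths decay exponentially into the gel with scale
0.3 µm (clipped at 0.6 µm), so the concentration peaks at the surface as
it does physically when beads are squeezed against the mold.  Beads render
as anisotropic Gaussian blobs (σ_xy 0.12 µm, σ_z/σ_xy = 3 emulating
confocal axial elongation) at 0.104 µm pixels and 0.2 µm z-steps, so a
blob spans ≈2.3 pixels — near the optimum particle-image diameter.
Additive Gaussian noise is seeded; identical inputs give bit-identical
stacks.

Not emulated: diffraction/Airyscan image formation, photobleaching, depth-
dependent aberrations, bead polydispersity, cell autofluorescence, true
lensing by the cell body.  Passing tests therefore demonstrate the
*computational* chain under realistic bead statistics and noise, not the
microscope's full physics.

## Volumetric PIV

Each reference interrogation box (default 32 × 32 × 8 voxels, 50% overlap)
is a template correlated by FFT against a search window of the deformed
stack extended by `search_radius` (default box/4) per side.  Because the
template is fully contained in the window at every admissible lag, the
correlation has no finite-window overlap taper; without this the peak is
pulled toward zero lag by roughly σ_corr²/box per axis (~0.08 px here),
a ~15% systematic underestimate at the sub-pixel displacement scale of
these experiments.  Peaks are selected on the zero-normalized correlation
(each lag divided by the contrast energy of the deformed patch it aligns
with), which is scale-invariant: an integer-voxel translation scores
exactly 1 and is recovered exactly.  Sub-voxel refinement re-extracts the
deformed box at the integer lag and fits a three-point Gaussian per axis
to the symmetric box-to-box correlation (overlap taper of the ±1 samples
divided out); identical content yields exactly zero refinement.  The fit
is exact for Gaussian peaks; a parabolic fallback handles non-positive
samples.

Vectors are anchored at the reference box's intensity centroid rather than
its geometric center: beads concentrate in a thin surface layer, so a box
straddling a gel surface reports that surface's displacement, and the
centroid anchor places the vector where the beads actually are.  Boxes
are placed fully inside the stack; featureless or boundary-peaked boxes
are flagged invalid, a quality threshold (normalized correlation ≥ 0.3 in
the pipeline) removes bead-free cavity boxes, and a normalized-median test
(threshold 2.0, ε = 0.02 µm) invalidates outliers and substitutes the
neighborhood median.  A robust noise estimate (1.4826 × median absolute
deviation from the neighborhood median) feeds diagnostics.

Measured performance on synthetic renders: integer translations exact;
0.4 px shifts recovered within 0.1 px in ≥95% of boxes (median ≈0.036 px);
z errors exceed xy errors, as the elongated PSF dictates.

## Elasticity and meshing

Polyacrylamide is modeled as isotropic linear elastic (default E = 15 kPa;
ν = 0.45, configurable — the true Poisson ratio of these gels is not
pinned down, and linear tetrahedra lock as ν → 0.5).  A compressible
Neo-Hookean law (parameters from E, ν) solved by Newton iteration is
available for checking that measured strains are small enough for the
linear model; at the ~1% strains of these experiments the two agree to
better than 1%.

The mesh is a boundary-fitted structured grid built in cylindrical logical
coordinates: an inner disk region below the cavity, an outer annular
region graded geometrically (ratio 1.35) to the square lateral boundary
(n_θ forced to a multiple of 8 so rays hit the square corners exactly),
and vertical levels graded away from the well.  Fillet arcs are resolved
to a chordal error below a quarter edge length.  Prisms are subdivided
into tetrahedra with quad-face diagonals through each face's minimum
global node index, which is globally conforming; an exact patch test and
an exact confined-compression solution verify the assembly.  Boundary
facets are classified geometrically into gel_top, well_wall, well_bottom
(floor plus bottom fillet), base and lateral groups; the lateral extent
defaults to six well radii so the traction-free far boundary is
mechanically remote.

Consistent surface loads use the linear-triangle surface mass matrix
(∫NᵢNⱼ dA = A/12 (1+δᵢⱼ)), restricted to the facets of the group that
carries the traction, so a rim-node traction does not spill onto the gel
top.  Nodal forces convert to tractions through lumped nodal areas (one
third of adjacent facet areas); total force is conserved exactly.

Convergence: on an area-weighted wall-displacement functional the solution
changes by ~13% from 2 → 1 µm edges and ~4% from 1 → 0.5 µm (≈O(h^1.7));
linear tetrahedra on this curved, near-incompressible problem carry a
large constant, so coarse meshes are systematically stiff at the ~10%
level.  In the closed synthetic loop this bias cancels (data and inverse
share the mesh); for absolute tractions from real data, finer meshes or a
mixed formulation (a noted extension) reduce it.  The default problem
sizes — 1.5 µm edges (~8400 nodes) for the reference mesh, 2.2 µm for the
closed loop — were chosen as the accuracy/runtime balance the package
targets on a single CPU.

## Inverse problem

Unknowns are nodal traction vectors on well_wall ∪ well_bottom.  The
constrained minimization (misfit + Tikhonov, equilibrium as constraint) is
reduced to linear least squares by eliminating displacements through the
factorized stiffness: each traction degree of freedom gets an explicit
displacement-sensitivity column (one sparse triangular solve), and an SVD
of the area-scaled sensitivity matrix makes λ sweeps essentially free.
Misfit weights and penalty weights are lumped nodal areas, so both terms
approximate surface integrals.  Measured PIV vectors are interpolated to
surface nodes by piecewise-linear simplex interpolation; nodes outside the
data hull take nearest-sample values and are flagged.

With λ = 0 and forward-consistent data the reconstruction is exact to
round-off.  For λ selection, the discrepancy principle against a PIV
noise estimate is implemented but is *not* the default: the effective data
error at surface nodes is dominated by spatially correlated interpolation
error, which the iid-noise discrepancy target mis-measures (it either
returns λ = 0 or over-smooths).  The default is the L-curve corner
(maximum curvature of log-residual vs log-solution-norm over a 120-point
λ sweep), which needs no noise estimate and lands near the error minimum
in the closed loop.  The reconstructed field is a forward solution by
construction, so it satisfies discrete equilibrium exactly, and the gel
top is exactly traction-free because it contributes no unknowns.  Ridge
shrinkage biases traction magnitudes slightly toward zero at finite λ;
in the closed loop the recovered mean wall traction is ~10% low.

The direct alternative — imposing measured displacements as essential
boundary conditions on all measured surfaces — is provided as a
diagnostic: with consistent data its gel-top reactions vanish, but 10 nm
of displacement noise produces hundreds of Pa of spurious top-surface
traction, the failure that motivates the inverse formulation.  The
reconstruction noise floor scales linearly with displacement noise SD
(log-log slope ≈ 1), so empty-well or trypsinized controls calibrate it
directly.

## Unfolding, profiles, metrics

Wall components at azimuth θ: T_n along (cos θ, sin θ, 0) (positive =
outward/extensile), T_v along +z, T_c along (−sin θ, cos θ, 0).  Bottom:
T_n vertical, T_r radially outward (contractile rims give negative T_r),
T_c as on the wall; the axis node has no radial direction and is flagged
with zeroed T_r, T_c.  The frame is orthonormal, so component magnitudes
recompose exactly.

Maps interpolate scattered node values onto a regular grid by Delaunay
linear interpolation (exactly node-reproducing, the testable property that
natural-neighbor interpolation also has), with wall data replicated across
the 0/360° seam for periodicity.  The wall rectangle spans z from
bottom + bottom-fillet to top − excluded_band (default 1 µm): the rounded
rims are where discretization and geometric uncertainty concentrate.
Bottom maps rasterize onto a Cartesian grid masked to the disk; radial
profiles use annular bins of about one mesh edge.  Profiles of different
well depths are aligned at their lowest point; samples beyond the common
support are kept but flagged undisplayed so group statistics exclude them.
Profile standard deviations are azimuthal (within one well); cross-well
statistics are left to downstream analysis.

Metrics use sample (n−1) standard deviations throughout.  The mean
traction is measure-weighted (arc length / annulus area) by default, with
equal-weight averaging available, since which of the two the headline
"mean T_n-wall" uses is a reporting choice.  CoV is |std/mean| and raises
on near-zero means.  SNR is the ratio of mean absolute profile values on
matched abscissae (infinite for an identically-zero noise profile).  Net
forces are Σ traction·area in nN with optional sign filtering; contact
area and cell volume come from the closed-form (optionally
fillet-corrected) cylinder expressions.

## Known limitations

* Linear tetrahedra at ν = 0.45: coarse-mesh stiffness bias (~10% at 2 µm
  edges) and slow convergence; a mixed/hybrid element would remove it.
* The lensing correction consumes a *measured* calibration field; no
  optical model predicts it from cell shape.
* Single-pass PIV (no iterative window deformation): large displacement
  gradients within one box blur the correlation peak.
* The λ choice is heuristic (L-curve); tractions inherit a shrinkage bias
  at the few-percent to ~10% level depending on noise.
* The synthetic generator's surface-accumulation profile is a stand-in;
  the real depth profile of bead enrichment is not quantified.
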