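# Methods

This note records the model behind `voxsbml`, the conventions and numerical
choices it commits to, and what its synthetic test inputs do and do not show
about real microscopy data.

## The geometry model

The package represents cellular geometry as a single labelled voxel grid.
Each cellular component supplied as a binary mask becomes a **volume domain
type**; the extracellular space (`EC`) is never supplied but synthesised as
the background complement, so two input masks (cytosol, nucleus) yield a
three-type model. The grid is indexed `(x, y, z)` with TIFF pages as
z-slices; a 2D image is a stack of z-extent 1. Physical voxel spacing
`(dx, dy, dz)` comes from TIFF resolution tags and ImageJ-style metadata
(z step), defaulting to isotropic 1 with a warning so synthetic grids work
unannotated. Voxel `(i, j, k)` sits at physical position
`((i+0.5)dx, (j+0.5)dy, (k+0.5)dz)` — the voxel-centre convention — and the
coordinate system spans `[0, extent·spacing]` per axis.

**Sampled values.** With `N` volume types (EC included) the type at position
`d` of the depth order receives the 8-bit value `d·⌊255/N⌋`; the canonical
two-mask model therefore gets EC = 0, Cyt = 85, Nuc = 170, and deeper regions
always carry strictly larger values. The position in the *total* depth order
is used rather than the raw containment depth: two sibling organelle types at
equal containment depth would otherwise collide on one value, violating the
distinctness that the whole encoding rests on. On nesting chains the two
definitions coincide.

**Domains and connectivity.** A domain is a maximal 26-connected region of
one type (8-connected in-plane for 2D inputs, which is the same thing on a
single-slice grid); this is the particle-analysis convention of mainstream
image software. Background/hole connectivity is the complementary
6-connectivity, avoiding the classic paradox where a closed 26-connected
surface fails to separate 26-connected background. Adjacency between domains
is stricter than domain connectivity: two domains are adjacent only when they
share a voxel *face* (6-neighbourhood), because a zero-thickness membrane
with diagonal-only contact would have zero area. Domain ids are
deterministic: per-type ordinals by descending voxel count, ties by
lexicographically smallest minimum voxel coordinate.

**Interior points.** Each domain's interior point is its voxel with maximal
city-block distance to the nearest differently-valued voxel (ties:
lexicographic on `(x, y, z)`). For a grid of a single uniform value the
distance is measured to the grid boundary instead, so the geometric centre
wins; either way the chosen voxel provably carries the domain's own value.

**Membranes.** One membrane domain is created per adjacent pair of volume
*domains*, under one shared membrane domain type per *type* pair — two nuclei
touching one cytosol give `NM0` and `NM1` under the single type `NM`. The
canonical names `PM` (Cyt|EC) and `NM` (Nuc|Cyt) are used where they apply;
other pairs get `<inner>_<outer>_membrane`. Membranes carry no voxels and no
sampled value: they are encoded purely as a dimension-2 domain type plus two
`adjacentDomains` records (membrane↔inner, membrane↔outer). A strictly
nested chain of `n` volume types yields exactly `n − 1` membranes.

## Preprocessing

Real segmentations need repair before merging; all repairs are formulated as
border flood fills rather than kernel-based morphology, which reproduces the
intended effect without committing to arbitrary structuring-element sizes:

* **Hole filling** sets every background component not 6-connected to the
  image border to foreground. Axes of extent 1 are degenerate (a planar image
  embedded in 3D); their faces are not treated as border, otherwise no 2D
  image could ever contain a hole.
* **Gap filling** overlays a nested pair of masks and assigns enclosed
  background (e.g. a shell of missed voxels between nucleus and cytosol) to
  the **outer** mask. Outer wins so the inner organelle's own segmented
  boundary is preserved; the pipeline applies this to each direct
  parent/child pair of the hierarchy.
* **Overlap resolution** makes masks pairwise disjoint, the innermost
  claimant winning each voxel — consistent with the nucleus keeping its own
  value inside the cytosol. Both operations preserve the union of foreground.
* **z interpolation** resamples an anisotropic stack (`dz > dx = dy`, the
  typical confocal case; `dx ≠ dy` is rejected as unsupported) by
  nearest-neighbour slice replication with integer factor `k = round(dz/dx)`:
  output slice `j` copies the input slice nearest to `(j+0.5)/k − 0.5`. An
  integer factor keeps the operation exactly invertible slice-wise, never
  invents voxel values, and multiplies the foreground count by exactly `k`.

**Containment** is decided on mask *footprints* (foreground with enclosed
background filled): A is inside B iff A's footprint is a subset of B's. This
makes a gapped or shell-shaped cytosol still contain its nucleus. Masks whose
footprints partially overlap with neither containing the other have no
consistent nesting and raise an error. Siblings at equal depth are ordered by
descending voxel count for deterministic ids.

## SBML serialization

Documents are SBML Level 3 Version 1 with the Spatial Processes package
declared `required`. One compartment per domain type (dimension 3 for
volumes with size `voxel_count·dx·dy·dz`, making the document
simulation-ready; dimension 2 for membranes), linked via compartment
mappings. The voxel array is written as one uncompressed `sampledField` of
space-separated integers, x-index fastest, then y, then z — the row-major
raster convention — with one `sampledVolume` per **volume** type only;
membranes never appear in the sampled field. Import accepts only L3V1
documents with the spatial package and uncompressed (trivially decodable)
sampled fields, rejecting anything else with a specific error. User-supplied
names are sanitised to the SBML SId grammar (non-alphanumerics → `_`).
Kinetic laws are infix expressions parsed to MathML; every identifier they
reference must already exist, and unknown ones are reported by name.

## Validation

Two offline validators return issue lists (severity, stable rule id,
message, offending id) rather than raising: structural checks (unique ids,
species→compartment, parameter→species, reaction references, math parsing)
and spatial semantics (sampled-value uniqueness, no orphan grid values,
every populated type has domains and exactly one compartment, adjacency
references resolve, membranes join two distinct domains and never collide
with a volume type, interior points carry their domain's value, positive
spacing). Biologically suspicious adjacency — two types whose containment
depths differ by more than one, e.g. a nucleus touching the extracellular
space — is a *warning*: it flags a probable segmentation breach but never
blocks export. Export refuses on error-severity issues unless forced.

## Synthetic inputs

The generators produce spheres (and decimated stacks) because every claimed
property — containment, adjacency, component and membrane counts, gap
topology, replication arithmetic — is then analytically checkable; they are
deterministic by construction. The default study condition is a 32×32×32
grid with cytosol radius 12 and nucleus radius 6 voxels (a cell roughly
one-third of the field of view, nucleus half the cell radius — proportions
typical of adherent cultured cells), gap width 2 voxels, z-decimation
factor 4, and a 48×48×32 grid for the two-nuclei case. What passing tests do
**not** show: robustness to ragged real segmentation boundaries, partial
voluming, touching cells, or non-spherical topology (invaginations,
handles). The preprocessing and labelling operations are oracle-checked on
1,000 random grids up to 6×6×6 precisely to cover irregular shapes the
sphere fixtures cannot.

## Numerical and scale choices

Oracle comparisons use BFS flood fills and all-pairs voxel scans written
independently of the vectorised scipy implementation paths. Test problem
sizes (32³ fixtures, ≤6³ random grids) keep the full suite around ten
seconds while still exercising every code path; the pipeline itself is
linear in voxel count and handles typical microscopy stacks. There is no
randomness anywhere in the pipeline; the acceptance script's `--seed` is
interface uniformity only.

## Known limitations

* Gap filling is applied along the derived nesting chain's consecutive
  parent/child pairs; a gap between a type and a *grand*-parent (or between
  siblings' shared parent when the chain interleaves them) is closed only
  via the hole-filling step that precedes it.
* The depth used for biological-consistency warnings inside
  `validate_spatial` is the total-order position; for models with sibling
  types the pipeline's own warnings (computed from true containment depths)
  are authoritative.
* Only sampled-field (voxel) geometry is produced — no mesh or CSG
  representations — and only the spatial package is read or written (no
  comp/fbc, no SBML Level 2).
* Deflated sampled fields are rejected on import rather than decompressed.
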