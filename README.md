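# voxsbml

Spatial SBML models from segmented microscopy images.

Reaction–diffusion simulations are only as good as their geometry: a model of
molecular transport inside a cell should use the cell's *actual* shape, not an
idealised sphere. Modern microscopes produce exactly the raw material — z-stacks
that can be segmented into one binary mask per cellular component (cytosol,
nucleus, ...) — but turning a pile of masks into a simulation-ready geometry by
hand means assigning labels, finding which regions contain which, and placing a
membrane between every adjacent pair, a chore that grows as O(n²) in the number
of components.

`voxsbml` automates that conversion. It takes one binary mask per component
(single 2D images or 3D TIFF stacks) and produces an **SBML Level 3 Version 1**
document using the **Spatial Processes** package:

* masks are repaired first — holes filled, enclosed gaps between nested regions
  closed, anisotropic z-stacks resampled to isotropic voxels by
  nearest-neighbour slice replication;
* the containment hierarchy (extracellular ⊃ cytosol ⊃ nucleus ⊃ …) is derived
  automatically and the masks merged into a single grayscale geometry, one
  distinct 8-bit *sampled value* per volume domain type: with `N` types the
  type at depth `d` receives `d·⌊255/N⌋`, so the canonical two-mask model gets
  EC = 0, Cyt = 85, Nuc = 170;
* every maximal 26-connected region of a type becomes a *domain* with an
  interior point (the voxel deepest inside the region by city-block distance);
* zero-thickness *membranes* are created between every face-adjacent pair of
  volume domains (6-connectivity — a membrane needs a shared face to have
  area), encoded purely through `adjacentDomains` records: PM between cytosol
  and extracellular space, NM between nucleus and cytosol;
* species, parameters with spatial roles (diffusion, advection, boundary
  condition) and reactions — including membrane-local transport — can be added
  on top, and the whole model validates offline (structural SBML checks plus a
  semantic validator for the spatial constructs, with biological-consistency
  warnings such as "nucleus adjacent to the extracellular space").

The voxel array itself is written as an uncompressed `sampledField` (x fastest,
then y, then z), so any spatial-SBML-capable simulator can consume the
document, and `voxsbml` can re-import and edit its own output.

## Worked example

```python
from voxsbml import fixtures, masks_to_model, export_sbml

masks = fixtures.nested_spheres(extents=(32, 32, 32), radii=(12.0, 6.0))
result = masks_to_model(masks, name="nested_cell")
model = result.model
print("hierarchy:", " > ".join(result.hierarchy))
print("sampled values:", model.geometry.value_map)
print("domains:", [(d.id, d.voxel_count) for d in model.domains])
print("membranes:", [(m.id, f"{m.inner}|{m.outer}") for m in model.graph.membranes])
export_sbml(model, "nested_cell.xml")
```

prints

```
hierarchy: EC > Cyt > Nuc
sampled values: {'EC': 0, 'Cyt': 85, 'Nuc': 170}
domains: [('EC0', 25560), ('Cyt0', 6296), ('Nuc0', 912)]
membranes: [('NM0', 'Nuc0|Cyt0'), ('PM0', 'Cyt0|EC0')]
```

i.e. the background, the cytosol shell and the nucleus each became one domain
with its distinct grayscale value, and the nuclear and plasma membranes were
derived from the adjacency of those domains — no manual membrane enumeration.
`examples/` contains this and three more narrative scripts (membrane transport
editing, anisotropic-stack repair, gap filling).

The same conversion is available from a shell:

```sh
voxsbml convert --input Cyt=cytosol.tif --input Nuc=nucleus.tif \
    --nesting 'Cyt>Nuc' --out model.xml --graph adjacency.dot --image merged.tif
voxsbml edit model.xml --add-species A,Cyt,1.0
voxsbml validate model.xml
voxsbml info model.xml
```

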