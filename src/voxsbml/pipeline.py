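"""End-to-end conversion: segmented masks in, spatial SBML model out.

:func:`masks_to_model` chains the whole method — binarisation, hole filling,
z-interpolation, containment hierarchy, gap filling between each parent/child
pair, overlap resolution, grayscale merging, domain labelling, adjacency
detection, membrane creation — and returns the assembled
:class:`~voxsbml.sbml_spatial.SpatialModel` together with the biological
consistency warnings.  The CLI and the examples are thin wrappers around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import preprocess
from .geometry_builder import (
    EC_NAME,
    containment_depths,
    containment_hierarchy,
    label_domains,
    merge_masks,
)
from .image_io import ImageStack, ensure_binary
from .sbml_spatial import SpatialModel, build_model
from .topology import check_biology, create_membranes, detect_adjacency

__all__ = ["ConversionResult", "masks_to_model"]


@dataclass
class ConversionResult:
    """A converted model plus diagnostics a caller may want to surface."""

    model: SpatialModel
    hierarchy: list[str]
    warnings: list[str] = field(default_factory=list)


def masks_to_model(
    masks: dict[str, ImageStack],
    nesting: list[str] | None = None,
    name: str = "spatial_model",
    interpolate: bool = True,
    fill: bool = True,
) -> ConversionResult:
    """Convert named binary masks into a spatial SBML model.

    Parameters
    ----------
    masks
        One binary mask per cellular component, keyed by domain-type name
        (``"EC"`` is reserved: the extracellular space is synthesised as the
        background complement).
    nesting
        Containment order outermost → innermost (without EC).  Derived
        automatically from the masks when omitted.
    interpolate
        Resample anisotropic z-stacks to isotropic voxels first.
    fill
        Apply hole filling per mask and gap filling between each
        parent/child pair in the hierarchy.
    """
    work = {n: ensure_binary(m).copy_with(name=n) for n, m in masks.items()}
    if interpolate:
        work = {n: preprocess.interpolate_z(m) for n, m in work.items()}
    if fill:
        work = {n: preprocess.fill_holes(m) for n, m in work.items()}

    if nesting is None:
        order = containment_hierarchy(work)
        depths = containment_depths(work)
    else:
        order = [EC_NAME] + [n for n in nesting if n != EC_NAME]
        depths = {n: i for i, n in enumerate(order)}  # caller asserts a chain

    if fill:
        # close gaps between each direct parent/child pair, outermost first
        chain = order[1:]
        for parent, child in zip(chain, chain[1:]):
            if depths[child] == depths[parent] + 1:
                work[parent], work[child] = preprocess.fill_gap(work[parent], work[child])
    carved = preprocess.resolve_overlap(list(work.values()), order=order[1:])
    work = {m.name: m for m in carved}

    geom = merge_masks(work, order=order)
    domains = label_domains(geom)
    graph = detect_adjacency(geom, domains)
    graph = create_membranes(graph, geom.depth_order)
    warnings = check_biology(graph, depths)
    model = build_model(geom, domains, graph, name=name)
    return ConversionResult(model=model, hierarchy=order, warnings=warnings)
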