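"""Merging component masks into one labelled voxel geometry.

A spatial model's geometry is a single grayscale grid in which every volume
domain type (extracellular space, cytosol, nucleus, ...) owns one distinct
sampled value, and every maximal connected region of a domain type is a
*domain*.  This module derives the containment hierarchy of the input masks,
merges them into a :class:`LabeledGeometry`, labels the domains, and picks an
interior point for each — the raw material the topology and SBML layers build
on.

Conventions
-----------
* The extracellular domain type (``"EC"``) is synthesised as the background
  complement; no EC mask is ever supplied.  Two input masks (cytosol, nucleus)
  therefore yield a three-type model.
* With ``N`` volume domain types (EC included), the type at position ``d`` of
  the depth order receives sampled value ``d * (255 // N)`` — for the canonical
  nested cytosol/nucleus case: EC = 0, Cyt = 85, Nuc = 170.  Deeper regions get
  strictly larger values.
* Domains of one type are 26-connected (8-connected in 2-D) maximal regions,
  the particle-analysis convention of mainstream image software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import CapacityError, HierarchyError, InputError
from .image_io import FOREGROUND, ImageStack

__all__ = [
    "DomainTypeSpec",
    "LabeledGeometry",
    "Domain",
    "EC_NAME",
    "containment_hierarchy",
    "containment_depths",
    "merge_masks",
    "label_domains",
    "interior_point",
]

#: Reserved name of the synthesised extracellular domain type.
EC_NAME = "EC"

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class DomainTypeSpec:
    """One category of spatial region.

    Volume types (``dimension == 3``) carry a distinct 8-bit ``sampled_value``
    marking their voxels in the merged grid; membrane types (``dimension == 2``)
    have no voxels and hence no sampled value.
    """

    name: str
    dimension: int = 3
    sampled_value: int | None = None


@dataclass
class LabeledGeometry:
    """The merged grayscale geometry.

    Attributes
    ----------
    grid
        3-D integer array of sampled values, indexed ``(x, y, z)``.
    value_map
        Volume domain-type name -> sampled value; always contains ``EC: 0``.
    spacing
        Physical voxel spacing ``(dx, dy, dz)``.
    depth_order
        Volume domain-type names outermost -> innermost, EC first.
    """

    grid: np.ndarray
    value_map: dict[str, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    depth_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise InputError("geometry grid must be 3-D")
        present = set(np.unique(self.grid).tolist())
        known = set(self.value_map.values())
        orphans = present - known
        if orphans:
            raise InputError(f"grid values {sorted(orphans)} missing from value_map")

    @property
    def extents(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def value_of(self, domain_type: str) -> int:
        return self.value_map[domain_type]


@dataclass(frozen=True)
class Domain:
    """One maximal connected region of a domain type.

    ``id`` is ``"<domainType><k>"`` with a 0-based ordinal ``k`` assigned per
    domain type by descending voxel count (ties: lexicographically smallest
    minimum voxel coordinate), so ids are deterministic.
    """

    id: str
    domain_type: str
    voxel_count: int
    interior_point: tuple[int, int, int]


def _solid(fg: np.ndarray) -> np.ndarray:
    """Foreground with enclosed background filled — a region's spatial footprint
    including everything nested inside it."""
    return ndimage.binary_fill_holes(fg, structure=_STRUCT_6)


def _ancestor_sets(masks: dict[str, ImageStack]) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Per-mask strict ancestors (masks whose footprint contains it) and
    foreground voxel counts; raises on inconsistent nesting."""
    names = list(masks)
    for n in names:
        if n == EC_NAME:
            raise InputError(f"{EC_NAME!r} is reserved for the background complement")
        if not masks[n].is_binary():
            raise InputError(f"mask {n!r} is not binary; run ensure_binary first")
        if masks[n].extents != masks[names[0]].extents:
            raise InputError("all masks must share the same extents")

    solids = {n: _solid(masks[n].voxels == FOREGROUND) for n in names}
    counts = {n: int((masks[n].voxels == FOREGROUND).sum()) for n in names}

    ancestors: dict[str, set[str]] = {n: set() for n in names}
    for a in names:
        for b in names:
            if a == b:
                continue
            inter = solids[a] & solids[b]
            if not inter.any():
                continue
            a_in_b = bool((solids[a] & ~solids[b]).sum() == 0)
            b_in_a = bool((solids[b] & ~solids[a]).sum() == 0)
            if a_in_b and not b_in_a:
                ancestors[a].add(b)
            elif b_in_a and not a_in_b:
                ancestors[b].add(a)
            elif a_in_b and b_in_a:
                # identical footprints: deterministic order, larger mask outer
                outer, inner = sorted((a, b), key=lambda n: (-counts[n], n))
                ancestors[inner].add(outer)
            else:
                raise HierarchyError(
                    f"masks {a!r} and {b!r} partially overlap with neither "
                    "containing the other; fix the segmentation or the nesting"
                )
    return ancestors, counts


def containment_hierarchy(masks: dict[str, ImageStack]) -> list[str]:
    """Order mask names by strict containment depth, outermost first.

    EC (the implicit background complement) is prepended at depth 0.  Mask A is
    deeper than mask B when A's solid footprint (region plus everything nested
    in it) is contained in B's.  Siblings at equal depth are ordered by
    descending voxel count, ties by name.

    Raises
    ------
    HierarchyError
        If two masks' footprints overlap with neither containing the other —
        no consistent nesting exists then.
    """
    ancestors, counts = _ancestor_sets(masks)
    depth = {n: 1 + len(ancestors[n]) for n in masks}  # EC is depth 0
    ordered = sorted(masks, key=lambda n: (depth[n], -counts[n], n))
    return [EC_NAME] + ordered


def containment_depths(masks: dict[str, ImageStack]) -> dict[str, int]:
    """True containment depth per domain type: EC is 0, a mask's depth is one
    more than its number of strict ancestors.  Siblings share a depth, unlike
    their positions in :func:`containment_hierarchy`'s total order."""
    ancestors, _ = _ancestor_sets(masks)
    depths = {n: 1 + len(ancestors[n]) for n in masks}
    depths[EC_NAME] = 0
    return depths


def merge_masks(
    masks: dict[str, ImageStack], order: list[str] | None = None
) -> LabeledGeometry:
    """Combine disjoint binary masks into one grayscale geometry.

    Each volume domain type receives the sampled value ``d * (255 // N)`` where
    ``d`` is its position in the depth order and ``N`` the number of volume
    types including EC; every voxel gets the value of the unique mask covering
    it, 0 (EC) where none does.

    Parameters
    ----------
    masks
        Corrected (disjoint) binary masks keyed by domain-type name.
    order
        Depth order including EC, as from :func:`containment_hierarchy`.
        Computed automatically when omitted.

    Raises
    ------
    CapacityError
        With more than 255 volume types the 8-bit value space is exhausted.
    """
    if order is None:
        order = containment_hierarchy(masks)
    if order[0] != EC_NAME:
        order = [EC_NAME] + [n for n in order if n != EC_NAME]
    if set(order[1:]) != set(masks):
        raise InputError(f"depth order {order} does not match mask names {list(masks)}")

    n_types = len(order)
    if n_types > 255:
        raise CapacityError(
            f"{n_types} volume domain types exceed the 8-bit sampled-value space"
        )
    step = 255 // n_types if n_types > 1 else 0
    value_map = {name: d * step for d, name in enumerate(order)}

    if masks:
        first = next(iter(masks.values()))
        grid = np.zeros(first.extents, dtype=np.uint8)
        spacing = first.spacing
        claimed = np.zeros(first.extents, dtype=bool)
        for name in order[1:]:
            fg = masks[name].voxels == FOREGROUND
            if (fg & claimed).any():
                raise InputError(
                    f"mask {name!r} overlaps an earlier mask; run resolve_overlap first"
                )
            claimed |= fg
            grid[fg] = value_map[name]
    else:
        grid = np.zeros((1, 1, 1), dtype=np.uint8)
        spacing = (1.0, 1.0, 1.0)
        value_map = {EC_NAME: 0}
        order = [EC_NAME]
    return LabeledGeometry(grid=grid, value_map=value_map, spacing=spacing, depth_order=list(order))


def _components(geom: LabeledGeometry) -> tuple[list[Domain], np.ndarray]:
    """Label all domains and build the per-voxel domain-index grid.

    Returns the domain list (depth order, then per-type ordinal) and an int
    array mapping every voxel to its index in that list.
    """
    index_grid = np.full(geom.extents, -1, dtype=np.int32)
    domains: list[Domain] = []
    for name in geom.depth_order:
        value = geom.value_map[name]
        mask = geom.grid == value
        if not mask.any():
            continue
        labels, n = ndimage.label(mask, structure=_STRUCT_26)
        dist = _interior_distance(mask)
        comps = []
        for lab in range(1, n + 1):
            comp = labels == lab
            coords = np.argwhere(comp)
            count = len(coords)
            # interior point: max city-block distance to a differently-valued
            # voxel; ties by lexicographic (x, y, z)
            d_comp = np.where(comp, dist, -1)
            best = d_comp.max()
            pt = tuple(int(c) for c in np.argwhere(d_comp == best)[0])
            comps.append((count, tuple(coords[0]), lab, pt))
        comps.sort(key=lambda t: (-t[0], t[1]))
        for k, (count, _min_coord, lab, pt) in enumerate(comps):
            dom = Domain(
                id=f"{name}{k}", domain_type=name, voxel_count=count, interior_point=pt
            )
            index_grid[labels == lab] = len(domains)
            domains.append(dom)
    return domains, index_grid


def _interior_distance(mask: np.ndarray) -> np.ndarray:
    """City-block distance from each True voxel to the nearest False voxel.

    If the mask covers the whole grid there is no differently-valued voxel;
    distances are then measured to the outside of the grid so the geometric
    centre wins deterministically.
    """
    if mask.all():
        padded = np.pad(mask, 1)
        return ndimage.distance_transform_cdt(padded, metric="taxicab")[
            1:-1, 1:-1, 1:-1
        ]
    return ndimage.distance_transform_cdt(mask, metric="taxicab")


def label_domains(geom: LabeledGeometry) -> list[Domain]:
    """One :class:`Domain` per maximal 26-connected region per volume type.

    The EC complement is labelled like any other type (the border-connected
    background is normally ``EC0``).  Ordinals are assigned per type by
    descending voxel count, ties by lexicographically smallest minimum voxel
    coordinate, so the partition of the grid into domains is deterministic and
    complete: domain voxel counts sum to the grid size.
    """
    domains, _ = _components(geom)
    return domains


def interior_point(geom: LabeledGeometry, domain: Domain) -> tuple[int, int, int]:
    """Deepest voxel of a domain: maximal city-block distance to any
    differently-valued voxel, ties broken lexicographically on (x, y, z)."""
    if domain.voxel_count == 0:
        raise InputError(f"domain {domain.id} is empty")
    return domain.interior_point
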