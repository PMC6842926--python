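"""Deterministic synthetic mask generators.

Every input condition the pipeline must handle — clean nesting, a background
gap between nested regions, multiple connected components of one type, and
anisotropic z-sampling — is produced here analytically, from spheres on a
voxel grid.  Spheres are used because containment, adjacency, and component
counts are checkable in closed form; realism of cell shape is irrelevant to
the correctness properties being exercised.  Nothing here is random: identical
parameters give bit-identical masks.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError
from .image_io import FOREGROUND, ImageStack

__all__ = [
    "nested_spheres",
    "gapped_spheres",
    "anisotropic_stack",
    "multi_nucleus",
]


def _sphere(
    extents: tuple[int, int, int],
    center: tuple[float, float, float],
    radius: float,
) -> np.ndarray:
    if radius <= 0:
        return np.zeros(extents, dtype=bool)
    x, y, z = np.ogrid[: extents[0], : extents[1], : extents[2]]
    r2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return r2 <= radius**2


def _as_stack(fg: np.ndarray, spacing, name: str) -> ImageStack:
    return ImageStack(
        voxels=np.where(fg, FOREGROUND, 0).astype(np.uint8), spacing=spacing, name=name
    )


def nested_spheres(
    extents: tuple[int, int, int] = (32, 32, 32),
    center: tuple[float, float, float] | None = None,
    radii: tuple[float, float] = (12.0, 6.0),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> dict[str, ImageStack]:
    """Cytosol sphere with a concentric nucleus sphere inside.

    ``radii`` is (outer, inner), strictly decreasing; the cytosol mask is the
    full outer ball (the nucleus is carved out later by overlap resolution,
    as with real segmentations).

    Returns ``{"Cyt": ..., "Nuc": ...}``.
    """
    r_outer, r_inner = radii
    if not r_outer > r_inner:
        raise InputError(f"radii must be strictly decreasing, got {radii}")
    if center is None:
        center = tuple((e - 1) / 2 for e in extents)
    if any(c - r_outer < -0.5 or c + r_outer > e - 0.5 for c, e in zip(center, extents)):
        raise InputError(f"outer radius {r_outer} does not fit inside extents {extents}")
    cyt = _sphere(extents, center, r_outer)
    nuc = _sphere(extents, center, r_inner)
    return {
        "Cyt": _as_stack(cyt, spacing, "Cyt"),
        "Nuc": _as_stack(nuc, spacing, "Nuc"),
    }


def gapped_spheres(
    extents: tuple[int, int, int] = (32, 32, 32),
    radii: tuple[float, float] = (12.0, 6.0),
    gap_width: int = 2,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> dict[str, ImageStack]:
    """Nucleus sphere plus a cytosol *shell* starting ``gap_width`` voxels
    outside the nucleus surface — an enclosed background gap separates them,
    emulating a segmentation that undershot the cytosol's inner boundary.

    With ``gap_width == 0`` this degenerates to a shell touching the nucleus
    (same final pipeline result as :func:`nested_spheres`).
    """
    if gap_width < 0:
        raise InputError("gap_width must be >= 0")
    r_outer, r_inner = radii
    shell_inner = r_inner + gap_width
    if not r_outer > shell_inner:
        raise InputError(
            f"no room for a cytosol shell: outer radius {r_outer} must exceed "
            f"inner radius + gap = {shell_inner}"
        )
    center = tuple((e - 1) / 2 for e in extents)
    if any(c - r_outer < -0.5 or c + r_outer > e - 0.5 for c, e in zip(center, extents)):
        raise InputError(f"outer radius {r_outer} does not fit inside extents {extents}")
    nuc = _sphere(extents, center, r_inner)
    shell = _sphere(extents, center, r_outer) & ~_sphere(extents, center, shell_inner)
    return {
        "Cyt": _as_stack(shell, spacing, "Cyt"),
        "Nuc": _as_stack(nuc, spacing, "Nuc"),
    }


def anisotropic_stack(mask: ImageStack, keep_every_k: int) -> ImageStack:
    """Decimate z-slices to emulate a low-z-resolution acquisition.

    Keeps every ``k``-th slice (starting at 0) and scales dz by ``k``, so a
    subsequent nearest-neighbour interpolation restores the z-extent.
    """
    k = int(keep_every_k)
    if k < 2:
        raise InputError("keep_every_k must be >= 2")
    nz = mask.extents[2]
    if k >= nz:
        raise InputError(f"keep_every_k={k} must be smaller than z-extent {nz}")
    dx, dy, dz = mask.spacing
    out = mask.voxels[:, :, ::k]
    return mask.copy_with(voxels=np.ascontiguousarray(out), spacing=(dx, dy, dz * k))


def multi_nucleus(
    extents: tuple[int, int, int] = (48, 48, 32),
    centers: tuple[tuple[float, float, float], ...] = ((16.0, 24.0, 15.5), (32.0, 24.0, 15.5)),
    radii: tuple[float, float] = (20.0, 5.0),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> dict[str, ImageStack]:
    """One cytosol sphere containing several disjoint nucleus spheres.

    ``radii`` is (cytosol radius, nucleus radius); all nuclei share the radius
    and must be pairwise disjoint and strictly inside the cytosol.  The single
    ``"Nuc"`` mask then labels into one domain per nucleus.
    """
    r_cyt, r_nuc = radii
    cyt_center = tuple((e - 1) / 2 for e in extents)
    for i, a in enumerate(centers):
        if np.linalg.norm(np.subtract(a, cyt_center)) + r_nuc >= r_cyt:
            raise InputError(f"nucleus {i} at {a} is not strictly inside the cytosol")
        for b in centers[:i]:
            if np.linalg.norm(np.subtract(a, b)) <= 2 * r_nuc:
                raise InputError(f"nuclei at {a} and {b} overlap or touch")
    cyt = _sphere(extents, cyt_center, r_cyt)
    nuc = np.zeros(extents, dtype=bool)
    for c in centers:
        nuc |= _sphere(extents, c, r_nuc)
    return {
        "Cyt": _as_stack(cyt, spacing, "Cyt"),
        "Nuc": _as_stack(nuc, spacing, "Nuc"),
    }
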