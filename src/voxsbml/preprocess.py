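"""Segmentation clean-up before masks are merged into one geometry.

Real segmentations come with artifacts that would corrupt a voxel geometry:
holes inside a region, a background gap between a nucleus and the cytosol that
should enclose it, overlapping claims on the same voxel, and anisotropic
z-sampling (confocal stacks typically undersample z).  The four operations here
repair exactly those defects:

* :func:`fill_holes` — close enclosed background inside one mask;
* :func:`fill_gap` — assign enclosed background between a nested pair to the
  outer region;
* :func:`interpolate_z` — nearest-neighbour slice replication to isotropic
  voxels;
* :func:`resolve_overlap` — make masks pairwise disjoint, innermost claim wins.

Hole and gap detection use a background flood fill from the image border with
6-connectivity, the complementary connectivity to the 26-connected foreground
used for domain labelling; mixing the two avoids the classic topological
paradox of a closed surface that does not separate space.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import InputError
from .image_io import FOREGROUND, ImageStack

__all__ = ["fill_holes", "fill_gap", "interpolate_z", "resolve_overlap"]

logger = logging.getLogger(__name__)

# 6-connected structuring element (face neighbours only).
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def _require_binary(stack: ImageStack, op: str) -> None:
    if not stack.is_binary():
        raise InputError(f"{op} requires a binary (0/255) mask; run ensure_binary first")


def _fill(fg: np.ndarray) -> np.ndarray:
    """Foreground plus background not 6-connected to the image border.

    Axes of extent 1 are degenerate (a 2-D image embedded in 3-D): their
    boundary faces are out-of-plane, not background, so they are padded with
    foreground to keep the border flood fill from leaking through them.
    """
    pad = [(1, 1) if s == 1 else (0, 0) for s in fg.shape]
    if any(p != (0, 0) for p in pad):
        padded = np.pad(fg, pad, constant_values=True)
        filled = ndimage.binary_fill_holes(padded, structure=_STRUCT_6)
        sl = tuple(slice(1, -1) if p != (0, 0) else slice(None) for p in pad)
        return filled[sl]
    return ndimage.binary_fill_holes(fg, structure=_STRUCT_6)


def _enclosed_background(fg: np.ndarray) -> np.ndarray:
    """Background voxels not 6-connected to the image border, given foreground fg."""
    return _fill(fg) & ~fg


def fill_holes(mask: ImageStack) -> ImageStack:
    """Set every background component not connected to the image border to foreground.

    Foreground voxels are never removed; a mask without holes is returned
    unchanged (idempotent).
    """
    _require_binary(mask, "fill_holes")
    fg = mask.voxels == FOREGROUND
    filled = _fill(fg)
    return mask.copy_with(voxels=np.where(filled, FOREGROUND, 0).astype(np.uint8))


def fill_gap(outer: ImageStack, inner: ImageStack) -> tuple[ImageStack, ImageStack]:
    """Close the background gap between a nested pair of masks.

    Overlaying both masks, any background component unreachable from the image
    border is a segmentation gap (or hole); those voxels are added to the
    *outer* mask so the inner organelle's own boundary is preserved.  The inner
    mask is returned unchanged, and gapless input passes through untouched.

    Raises
    ------
    InputError
        If the masks' extents differ.
    """
    _require_binary(outer, "fill_gap")
    _require_binary(inner, "fill_gap")
    if outer.extents != inner.extents:
        raise InputError(
            f"extent mismatch: outer {outer.extents} vs inner {inner.extents}"
        )
    union = (outer.voxels == FOREGROUND) | (inner.voxels == FOREGROUND)
    gap = _enclosed_background(union)
    new_outer = (outer.voxels == FOREGROUND) | gap
    return (
        outer.copy_with(voxels=np.where(new_outer, FOREGROUND, 0).astype(np.uint8)),
        inner.copy_with(),
    )


def interpolate_z(stack: ImageStack) -> ImageStack:
    """Resample an anisotropic z-stack to (near-)isotropic voxels.

    With spacing ``(dx, dx, dz)`` and replication factor ``k = round(dz/dx)``,
    every output slice ``j`` is a copy of the input slice nearest to
    ``(j + 0.5)/k - 0.5`` — nearest-neighbour interpolation, so no voxel values
    are invented.  The output has z-extent multiplied by ``k`` and z-spacing
    ``dz/k``.  Isotropic input (``k = 1``) is returned unchanged.

    Works on binary and labelled stacks alike.

    Raises
    ------
    InputError
        If ``dx != dy`` — only z-axis undersampling is supported, the common
        anisotropy of confocal stacks.
    """
    dx, dy, dz = stack.spacing
    if not np.isclose(dx, dy):
        raise InputError(
            f"unsupported anisotropy: dx={dx} != dy={dy}; only z-axis "
            "undersampling (dz > dx = dy) is handled"
        )
    k = max(1, round(dz / dx))
    if k == 1:
        return stack.copy_with()
    nz = stack.extents[2]
    j = np.arange(nz * k)
    src = np.clip(np.rint((j + 0.5) / k - 0.5).astype(int), 0, nz - 1)
    out = stack.voxels[:, :, src]
    return stack.copy_with(voxels=np.ascontiguousarray(out), spacing=(dx, dy, dz / k))


def resolve_overlap(
    masks: Sequence[ImageStack], order: Sequence[str] | None = None
) -> list[ImageStack]:
    """Make masks pairwise disjoint: a voxel claimed by several masks is kept
    only in the innermost (deepest) one.

    Parameters
    ----------
    masks
        Binary masks of identical extents.
    order
        Mask names from outermost to innermost.  Defaults to the order of
        ``masks`` itself.

    Returns
    -------
    list of ImageStack
        Masks in the same order as the input, with every inner region carved
        out of all masks outer to it.  The union of the outputs equals the
        union of the inputs.
    """
    if not masks:
        return []
    for m in masks:
        _require_binary(m, "resolve_overlap")
        if m.extents != masks[0].extents:
            raise InputError("resolve_overlap requires masks of identical extents")
    if order is not None:
        by_name = {m.name: m for m in masks}
        missing = [n for n in order if n not in by_name]
        if missing or len(order) != len(masks):
            raise InputError(f"order {list(order)} does not match mask names")
        ordered = [by_name[n] for n in order]
    else:
        ordered = list(masks)

    claimed_deeper = np.zeros(ordered[0].extents, dtype=bool)
    carved: list[ImageStack] = [None] * len(ordered)  # type: ignore[list-item]
    for i in range(len(ordered) - 1, -1, -1):  # innermost first
        m = ordered[i]
        fg = m.voxels == FOREGROUND
        kept = fg & ~claimed_deeper
        if fg.any() and not kept.any():
            logger.warning(
                "mask %r is entirely covered by deeper masks and becomes empty",
                m.name,
            )
        claimed_deeper |= fg
        carved[i] = m.copy_with(voxels=np.where(kept, FOREGROUND, 0).astype(np.uint8))
    return carved
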