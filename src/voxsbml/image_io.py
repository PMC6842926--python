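"""Reading and writing voxel image stacks.

The unit of input is the :class:`ImageStack`: a 3-D integer voxel grid indexed
``(x, y, z)`` together with its physical voxel spacing ``(dx, dy, dz)``.  A 2-D
image is a stack with z-extent 1.  Segmented masks are binary 8-bit images with
foreground 255 and background 0; :func:`ensure_binary` normalises any nonzero
convention to that one.

TIFF is the interchange format: multi-page TIFFs map pages to z-slices.  Voxel
spacing is recovered from the TIFF resolution tags (x/y) and, when present,
from ImageJ-style metadata (z step); images without spacing metadata default to
isotropic ``(1, 1, 1)`` with a warning so purely synthetic grids round-trip
without fuss.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import InputError

__all__ = ["ImageStack", "read_stack", "write_stack", "ensure_binary", "FOREGROUND"]

logger = logging.getLogger(__name__)

#: 8-bit foreground value of a binary mask.
FOREGROUND = 255


@dataclass
class ImageStack:
    """A voxel grid with physical spacing.

    Parameters
    ----------
    voxels
        Integer array indexed ``[x, y, z]``.  A 2-D array is promoted to a
        single-slice stack.
    spacing
        Physical edge lengths ``(dx, dy, dz)`` of one voxel, in arbitrary but
        consistent units.  All components must be positive.
    name
        Identifier of the cellular component this mask represents (e.g.
        ``"Cyt"``, ``"Nuc"``).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[:, :, np.newaxis]
        if self.voxels.ndim != 3:
            raise InputError(
                f"voxel grid must be 2-D or 3-D, got {self.voxels.ndim}-D"
            )
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise InputError(f"voxel grid must be integer, got {self.voxels.dtype}")
        if min(self.voxels.shape) < 1:
            raise InputError(f"all extents must be >= 1, got {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InputError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def extents(self) -> tuple[int, int, int]:
        """Grid size ``(nx, ny, nz)``."""
        return self.voxels.shape  # type: ignore[return-value]

    def is_binary(self) -> bool:
        """True if every voxel is 0 or :data:`FOREGROUND`."""
        return bool(np.isin(self.voxels, (0, FOREGROUND)).all())

    def copy_with(self, voxels: np.ndarray | None = None, spacing=None, name=None) -> "ImageStack":
        """Return a copy, optionally replacing fields."""
        return ImageStack(
            voxels=self.voxels.copy() if voxels is None else voxels,
            spacing=self.spacing if spacing is None else spacing,
            name=self.name if name is None else name,
        )


def _spacing_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Extract (dx, dy, dz) from TIFF resolution tags and ImageJ metadata."""
    page = tif.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    yres = tags.get("YResolution")
    if xres is None or yres is None:
        return None
    unit = tags.get("ResolutionUnit")
    if (
        unit is not None
        and unit.value == tifffile.RESUNIT.NONE
        and xres.value == (1, 1)
        and yres.value == (1, 1)
        and not (tif.imagej_metadata and "spacing" in tif.imagej_metadata)
    ):
        return None  # writer defaults, not real calibration

    def _to_length(res) -> float | None:
        num, den = res.value
        if num == 0:
            return None
        return den / num  # resolution is pixels per unit; length is its inverse

    dx = _to_length(xres)
    dy = _to_length(yres)
    if dx is None or dy is None:
        return None
    dz = None
    meta = tif.imagej_metadata
    if meta and "spacing" in meta:
        dz = float(meta["spacing"])
    if dz is None or dz <= 0:
        dz = 1.0
    return (dx, dy, dz)


def read_stack(path, name: str = "") -> ImageStack:
    """Read a single- or multi-page grayscale TIFF into an :class:`ImageStack`.

    Pages are z-slices; the returned z-extent equals the page count.  Spacing is
    taken from the file's resolution metadata when present, otherwise it
    defaults to ``(1, 1, 1)`` with a warning.

    Raises
    ------
    InputError
        If the file is unreadable or contains multi-channel (RGB) pages; split
        channels upstream, one mask per component.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            if tif.pages[0].samplesperpixel > 1:
                raise InputError(
                    f"{path} is a multi-channel (RGB) image; pre-split channels "
                    "into one single-channel mask per component"
                )
            arr = tif.asarray()
            spacing = _spacing_from_tiff(tif)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise InputError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[np.newaxis, :, :]
    if arr.ndim != 3:
        raise InputError(f"{path}: unsupported TIFF layout {arr.shape}")
    if spacing is None:
        warnings.warn(
            f"{path}: no resolution metadata; assuming isotropic spacing (1, 1, 1)",
            stacklevel=2,
        )
        spacing = (1.0, 1.0, 1.0)
    # tifffile returns (z, y, x); transpose to the (x, y, z) convention.
    voxels = np.ascontiguousarray(arr.T)
    return ImageStack(voxels=voxels, spacing=spacing, name=name or path.stem)


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as a multi-page 8-bit grayscale TIFF.

    Spacing is stored in the resolution tags and ImageJ-style metadata so that
    ``read_stack(write_stack(s))`` reproduces both voxels (bit-exactly) and
    spacing.

    Raises
    ------
    InputError
        If any voxel value falls outside the 8-bit range.
    """
    path = Path(path)
    vox = stack.voxels
    if vox.min() < 0 or vox.max() > 255:
        raise InputError(
            f"voxel values [{vox.min()}, {vox.max()}] exceed the 8-bit range; "
            "cannot write an 8-bit TIFF"
        )
    dx, dy, dz = stack.spacing
    data = np.ascontiguousarray(vox.astype(np.uint8).T)  # back to (z, y, x)
    try:
        tifffile.imwrite(
            path,
            data,
            imagej=True,
            resolution=(1.0 / dx, 1.0 / dy),
            metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
        )
    except OSError as exc:
        raise InputError(f"cannot write TIFF {path}: {exc}") from exc
    return path


def ensure_binary(stack: ImageStack) -> ImageStack:
    """Map every nonzero voxel to :data:`FOREGROUND`; zero stays zero.

    Idempotent, and preserves the zero set exactly, so masks binarised with any
    foreground convention (1, 17, 255, ...) end up in the canonical 0/255 form.
    """
    out = np.where(stack.voxels != 0, FOREGROUND, 0).astype(np.uint8)
    return stack.copy_with(voxels=out)
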