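"""Reading, writing and geometric splitting of dual-view polarization frames.

A polarization-resolved wide-field acquisition places both emission
polarizations side by side on one camera chip: a 2048x2048 frame whose
left 1024x2048 half is the perpendicular channel and whose right half is
the parallel channel.  This module handles the raw TIFF I/O and the fixed
geometric split; no pixel values are altered here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "RawDualViewFrame",
    "PolarizedFramePair",
    "RoiMask",
    "read_frame",
    "split_dual_view",
    "assemble_dual_view",
    "write_map",
    "read_map",
]


@dataclass
class RawDualViewFrame:
    """A single camera frame holding both polarization channels side by side.

    Parameters
    ----------
    pixels : ndarray of shape (height, width)
        Raw camera counts.  Row-major, origin at the top-left corner.
    bit_depth : int
        Bit depth of the camera ADC (8 or 16 for the supported inputs).
    """

    pixels: np.ndarray
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D frame, got ndim={self.pixels.ndim}")
        if np.issubdtype(self.pixels.dtype, np.integer):
            if self.pixels.min() < 0:
                raise ValueError("camera counts must be non-negative")
            if self.pixels.max() > 2**self.bit_depth - 1:
                raise ValueError(
                    f"pixel values exceed the stated {self.bit_depth}-bit range"
                )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PolarizedFramePair:
    """Parallel / perpendicular intensity images sharing one pixel grid.

    ``registered`` stays False until a channel transform has resampled the
    perpendicular half onto the parallel grid.  ``valid`` marks pixels that
    remain in-field after that resampling.
    """

    parallel: np.ndarray
    perpendicular: np.ndarray
    registered: bool = False
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.parallel = np.asarray(self.parallel, dtype=float)
        self.perpendicular = np.asarray(self.perpendicular, dtype=float)
        if self.parallel.shape != self.perpendicular.shape:
            raise ValueError(
                "parallel and perpendicular halves must have identical shape, "
                f"got {self.parallel.shape} vs {self.perpendicular.shape}"
            )
        if self.valid is None:
            self.valid = np.ones(self.parallel.shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.parallel.shape


@dataclass
class RoiMask:
    """Cell label image (0 = background, k > 0 = cell k) with optional nuclei.

    Nuclear pixels of cell k must be a subset of cell-k pixels.
    """

    labels: np.ndarray
    nucleus_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("ROI labels must be an integer label image")
        if self.nucleus_labels is not None:
            self.nucleus_labels = np.asarray(self.nucleus_labels)
            if self.nucleus_labels.shape != self.labels.shape:
                raise ValueError("nucleus label image must match the cell label image shape")
            outside = (self.nucleus_labels > 0) & (self.labels != self.nucleus_labels)
            if outside.any():
                raise ValueError("nucleus pixels must lie inside their cell")

    def cell_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]


def read_frame(path: str | Path) -> RawDualViewFrame:
    """Read a single-plane grayscale TIFF as a raw dual-view frame.

    The pixel values are returned exactly as stored; the bit depth is taken
    from the file's sample format.  RGB or multi-plane TIFFs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        arr = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise IOError(f"could not read TIFF {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-plane grayscale TIFF, got shape {arr.shape}"
        )
    if np.issubdtype(arr.dtype, np.integer):
        bit_depth = arr.dtype.itemsize * 8
    else:
        bit_depth = 32
    return RawDualViewFrame(pixels=arr, bit_depth=bit_depth)


def split_dual_view(
    frame: RawDualViewFrame, left_is_perpendicular: bool = True
) -> PolarizedFramePair:
    """Split a dual-view frame into its two polarization halves.

    By default the left half is the perpendicular channel and the right half
    the parallel channel; ``left_is_perpendicular=False`` flips the
    convention for hardware with the opposite layout.  Pixel values are
    copied unchanged and the pair starts unregistered.
    """
    if frame.width % 2 != 0:
        raise ValueError(f"frame width {frame.width} is odd; cannot split into halves")
    half = frame.width // 2
    left = frame.pixels[:, :half]
    right = frame.pixels[:, half:]
    if left_is_perpendicular:
        perpendicular, parallel = left, right
    else:
        perpendicular, parallel = right, left
    return PolarizedFramePair(
        parallel=parallel.copy(), perpendicular=perpendicular.copy(), registered=False
    )


def assemble_dual_view(
    pair: PolarizedFramePair,
    bit_depth: int = 16,
    left_is_perpendicular: bool = True,
) -> RawDualViewFrame:
    """Reassemble a frame pair into a single dual-view frame (inverse of split)."""
    if left_is_perpendicular:
        pixels = np.hstack([pair.perpendicular, pair.parallel])
    else:
        pixels = np.hstack([pair.parallel, pair.perpendicular])
    return RawDualViewFrame(pixels=pixels, bit_depth=bit_depth)


def write_map(array: np.ndarray, path: str | Path) -> None:
    """Write a 2D map as 32-bit float TIFF; NaN-masked pixels are preserved."""
    arr = np.asarray(array, dtype=np.float32)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D map, got ndim={arr.ndim}")
    tifffile.imwrite(Path(path), arr)


def read_map(path: str | Path) -> np.ndarray:
    """Read back a 32-bit float map written by :func:`write_map`."""
    arr = tifffile.imread(Path(path))
    return np.asarray(arr, dtype=np.float32)
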