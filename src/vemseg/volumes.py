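"""Volumetric containers, stack/label I/O and anisotropy bookkeeping.

Serial-section EM stacks have an in-plane (X/Y) pixel size set by the
scan resolution and a coarser out-of-plane (Z) size set by the section
thickness.  All public arrays in this package use (X, Y, Z) axis order,
with the slice index along the last axis; multipage TIFF files store one
Z-slice per page, so arrays are transposed to (Z, Y, X) on disk.

The anisotropy factor ``rho = sz / sx`` is the single geometric quantity
the downstream stages need: it selects the 2D vs 3D feature extractor,
scales the across-slice regularization weight, and weights the Z term of
the surface-smoothing energy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

from .errors import FormatError, InvalidGeometryError

#: Default label ids: 0 is reserved for "unlabeled/ignore" in training data.
DEFAULT_LABEL_TABLE: dict[int, str] = {
    0: "unlabeled",
    1: "background",
    2: "synapse",
    3: "mitochondrion",
}

BACKGROUND, SYNAPSE, MITOCHONDRION = 1, 2, 3


def anisotropy_factor(voxel_size: tuple[float, float, float]) -> float:
    """Ratio of the Z voxel size to the (equal) X/Y voxel size.

    Parameters
    ----------
    voxel_size
        ``(sx, sy, sz)`` in nanometres; ``sx`` must equal ``sy``.

    Returns
    -------
    float
        ``sz / sx``.  1.0 means an isotropic stack.
    """
    sx, sy, sz = (float(v) for v in voxel_size)
    if sx <= 0 or sy <= 0 or sz <= 0:
        raise InvalidGeometryError(f"voxel sizes must be positive, got {voxel_size}")
    if sx != sy:
        raise InvalidGeometryError(f"X and Y voxel sizes must match, got sx={sx}, sy={sy}")
    return sz / sx


@dataclass(frozen=True)
class ImageStack:
    """A 3D grayscale volume with physical voxel size.

    ``data`` is float with axes (X, Y, Z); intensities are normalized to
    [0, 1] when loaded from integer sources.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise InvalidGeometryError(f"stack must be 3D, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise FormatError("stack contains non-finite intensities")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        anisotropy_factor(self.voxel_size)  # validates geometry

    @property
    def rho(self) -> float:
        """Anisotropy factor, always derived from ``voxel_size``."""
        return anisotropy_factor(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class LabelVolume:
    """Integer-coded per-voxel labels plus an id -> name table."""

    labels: np.ndarray
    label_table: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_TABLE))

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise InvalidGeometryError(f"label volume must be 3D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise FormatError(f"labels must be integer-coded, got dtype {labels.dtype}")
        table = {int(k): str(v) for k, v in dict(self.label_table).items()}
        present = set(np.unique(labels).tolist())
        missing = present - set(table)
        if missing:
            raise FormatError(f"label ids {sorted(missing)} missing from label table")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "label_table", table)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def ids(self, include_unlabeled: bool = False) -> list[int]:
        """Sorted label ids present in the volume."""
        out = sorted(int(i) for i in np.unique(self.labels))
        if not include_unlabeled:
            out = [i for i in out if i != 0]
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SLICE_SUFFIXES = {".tif", ".tiff", ".png"}


def _normalize_intensities(data: np.ndarray) -> np.ndarray:
    """Rescale integer intensities to [0, 1]; pass floats through."""
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        return data.astype(np.float64) / float(info.max)
    return data.astype(np.float64)


def _pages_to_xyz(pages: np.ndarray) -> np.ndarray:
    """(Z, Y, X) page-major storage -> (X, Y, Z) in-memory convention."""
    return np.ascontiguousarray(pages.transpose(2, 1, 0))


def _xyz_to_pages(volume: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(volume.transpose(2, 1, 0))


def _read_slices(directory: Path) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES)
    if not files:
        raise FormatError(f"no slice images found in {directory}")
    slices = []
    shape = None
    for f in files:
        try:
            img = np.asarray(iio.imread(f))
        except Exception as exc:  # noqa: BLE001 - report offending slice
            raise FormatError(f"unreadable slice {f.name}: {exc}") from exc
        if img.ndim == 3:  # collapse RGB(A) to grayscale by averaging color channels
            img = img[..., :3].mean(axis=-1).astype(img.dtype)
        if img.ndim != 2:
            raise FormatError(f"slice {f.name} is not a 2D image (shape {img.shape})")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise FormatError(
                f"ragged slice {f.name}: shape {img.shape} differs from first slice {shape}"
            )
        slices.append(img)
    return np.stack(slices, axis=0)  # (Z, Y, X)


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a grayscale stack from a multipage TIFF or a directory of slices.

    Slice files in a directory are ordered lexicographically = increasing Z.
    If the TIFF carries a voxel-size record written by :func:`write_stack`
    and ``voxel_size`` is not given, the stored value is used; otherwise
    isotropic 1 nm voxels are assumed.
    """
    path = Path(path)
    stored_vs = None
    if path.is_dir():
        pages = _read_slices(path)
    else:
        try:
            with tifffile.TiffFile(path) as tif:
                pages = tif.asarray()
                desc = tif.pages[0].description
            if desc:
                try:
                    meta = json.loads(desc)
                    stored_vs = tuple(meta["voxel_size_nm"])
                except (ValueError, KeyError, TypeError):
                    stored_vs = None
        except FileNotFoundError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"unreadable stack {path}: {exc}") from exc
        if pages.ndim == 2:
            pages = pages[None]
        if pages.ndim != 3:
            raise FormatError(f"{path} is not a grayscale stack (shape {pages.shape})")
    if voxel_size is None:
        voxel_size = stored_vs if stored_vs is not None else (1.0, 1.0, 1.0)
    data = _normalize_intensities(_pages_to_xyz(pages))
    return ImageStack(data=data, voxel_size=voxel_size)


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as a float32 multipage TIFF with voxel-size metadata."""
    meta = json.dumps({"voxel_size_nm": list(stack.voxel_size)})
    tifffile.imwrite(
        Path(path),
        _xyz_to_pages(stack.data).astype(np.float32),
        description=meta,
        photometric="minisblack",
    )


def _smallest_int_dtype(max_id: int) -> np.dtype:
    for dt in (np.uint8, np.uint16, np.uint32):
        if max_id <= np.iinfo(dt).max:
            return np.dtype(dt)
    return np.dtype(np.int64)


def write_labels(path: str | Path, volume: LabelVolume) -> None:
    """Write labels as an integer multipage TIFF; label table goes in the
    image description so the round trip is self-contained."""
    max_id = int(volume.labels.max(initial=0))
    dt = _smallest_int_dtype(max_id)
    meta = json.dumps({"label_table": {str(k): v for k, v in volume.label_table.items()}})
    tifffile.imwrite(
        Path(path),
        _xyz_to_pages(volume.labels).astype(dt),
        description=meta,
        photometric="minisblack",
    )


def read_labels(path: str | Path, label_table: Mapping[int, str] | None = None) -> LabelVolume:
    """Read an integer label volume written by :func:`write_labels`."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
            desc = tif.pages[0].description
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable label volume {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if not np.issubdtype(pages.dtype, np.integer):
        raise FormatError(f"{path} does not hold integer labels (dtype {pages.dtype})")
    if label_table is None:
        table = None
        if desc:
            try:
                meta = json.loads(desc)
                table = {int(k): str(v) for k, v in meta["label_table"].items()}
            except (ValueError, KeyError, TypeError):
                table = None
        if table is None:
            present = np.unique(pages)
            table = {int(i): DEFAULT_LABEL_TABLE.get(int(i), f"label_{int(i)}") for i in present}
        label_table = table
    return LabelVolume(labels=_pages_to_xyz(pages), label_table=label_table)
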