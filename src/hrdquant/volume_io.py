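"""Reading and writing OCT volumes and label masks as ITK MetaImage.

Conventions owned by this module
--------------------------------
* Index order is ``(b, z, x)``: b-scan index (slow axis), axial depth
  (increasing from inner retina downward), lateral position.
* Spacings are carried in micrometres as ``(inter_slice, axial, lateral)``.
  MetaImage headers store spacing in millimetres; conversion happens here.
* Indices are 0-based and half-open; a voxel's physical coordinate is its
  centre, ``(index + 0.5) * spacing``.
* Intensities live in ``[0, 1]`` in memory (disk integers divided by the
  type maximum); label masks stay integer with classes {0, 1, 2}.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "OCTVolume",
    "LabelMask",
    "TOPCON_EXTENT_MM",
    "TOPCON_SHAPE",
    "topcon_spacing_um",
    "spacing_from_extent",
    "read_metaimage",
    "write_metaimage",
]

#: Macular cube extent (slow, axial, lateral) in mm and its pixel grid.
TOPCON_EXTENT_MM = (6.0, 2.0, 6.0)
TOPCON_SHAPE = (128, 885, 512)

BACKGROUND, HARD_EXUDATE, SMALL_HRD = 0, 1, 2
VALID_LABELS = frozenset({BACKGROUND, HARD_EXUDATE, SMALL_HRD})


def spacing_from_extent(
    extent_mm: tuple[float, float, float],
    shape: tuple[int, int, int],
) -> tuple[float, float, float]:
    """Voxel spacing in μm for a physical extent divided into a pixel grid.

    Parameters
    ----------
    extent_mm : physical size along (slow, axial, lateral) in millimetres.
    shape : number of voxels along the same axes.

    Returns
    -------
    tuple of float
        ``extent / shape`` per axis, in micrometres.
    """
    extent = np.asarray(extent_mm, dtype=float)
    shp = np.asarray(shape, dtype=float)
    if extent.shape != (3,) or shp.shape != (3,):
        raise ValueError("extent_mm and shape must be length-3")
    if np.any(extent <= 0):
        raise ValueError(f"extent_mm must be strictly positive, got {extent_mm}")
    if np.any(shp <= 0):
        raise ValueError(f"shape must be strictly positive, got {shape}")
    return tuple(extent / shp * 1000.0)


def topcon_spacing_um() -> tuple[float, float, float]:
    """Spacing of the default macular-cube geometry (6x6x2 mm, 128x885x512 px)."""
    return spacing_from_extent(TOPCON_EXTENT_MM, TOPCON_SHAPE)


def _check_grid(voxels: np.ndarray, spacing_um, what: str) -> None:
    if voxels.ndim != 3:
        raise ValueError(f"{what} must be 3D (b, z, x), got ndim={voxels.ndim}")
    if any(s < 1 for s in voxels.shape):
        raise ValueError(f"{what} dimensions must all be >= 1, got {voxels.shape}")
    sp = np.asarray(spacing_um, dtype=float)
    if sp.shape != (3,) or np.any(sp <= 0) or not np.all(np.isfinite(sp)):
        raise ValueError(f"spacing_um must be 3 strictly positive finite values, got {spacing_um}")


@dataclasses.dataclass
class OCTVolume:
    """A 3D OCT intensity grid with physical geometry.

    Attributes
    ----------
    voxels : (b, z, x) float array of intensities in [0, 1].
    spacing_um : (inter_slice, axial, lateral) voxel spacing in μm.
    origin : physical coordinate of voxel (0, 0, 0), μm.
    """

    voxels: np.ndarray
    spacing_um: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        _check_grid(self.voxels, self.spacing_um, "OCTVolume voxels")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_bscans(self) -> int:
        return self.voxels.shape[0]

    def bscan(self, b: int) -> np.ndarray:
        """The (z, x) image of b-scan ``b``."""
        return self.voxels[b]

    @property
    def inplane_pixel_area_um2(self) -> float:
        """Axial x lateral pixel area of the b-scan plane, μm²."""
        return self.spacing_um[1] * self.spacing_um[2]


@dataclasses.dataclass
class LabelMask:
    """Per-voxel class labels aligned to an :class:`OCTVolume`.

    Classes: 0 background, 1 hard exudate, 2 small HRD.
    """

    labels: np.ndarray
    spacing_um: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        _check_grid(self.labels, self.spacing_um, "LabelMask labels")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-typed, got {self.labels.dtype}")
        present = set(np.unique(self.labels).tolist())
        if not present <= VALID_LABELS:
            raise ValueError(f"labels outside {{0,1,2}}: {sorted(present - VALID_LABELS)}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def bscan(self, b: int) -> np.ndarray:
        return self.labels[b]

    def foreground(self) -> np.ndarray:
        """Boolean any-HRD mask."""
        return self.labels > 0


def _to_sitk(arr_bzx: np.ndarray, spacing_um, origin_um) -> sitk.Image:
    # SimpleITK's numpy bridge maps array axis 0 -> ITK z; our slow axis (b)
    # goes there so ElementSpacing reads (lateral, axial, inter_slice) in mm.
    img = sitk.GetImageFromArray(arr_bzx)
    sp = np.asarray(spacing_um, dtype=float) / 1000.0
    img.SetSpacing((sp[2], sp[1], sp[0]))
    og = np.asarray(origin_um, dtype=float) / 1000.0
    img.SetOrigin((og[2], og[1], og[0]))
    return img


def write_metaimage(obj: OCTVolume | LabelMask, path: str | Path) -> Path:
    """Write a volume or mask as MetaImage (.mha single file, or .mhd + .raw).

    Volumes are stored as unsigned 16-bit (intensity x 65535, rounded);
    masks as unsigned 8-bit labels. ``read_metaimage`` inverts the result
    bit-exactly for integer data.
    """
    path = Path(path)
    if path.suffix.lower() not in {".mha", ".mhd"}:
        raise ValueError(f"path must end in .mha or .mhd, got {path.suffix!r}")
    if isinstance(obj, LabelMask):
        arr = obj.labels.astype(np.uint8)
    elif isinstance(obj, OCTVolume):
        arr = np.round(np.clip(obj.voxels, 0.0, 1.0) * 65535.0).astype(np.uint16)
    else:
        raise TypeError(f"expected OCTVolume or LabelMask, got {type(obj).__name__}")
    img = _to_sitk(arr, obj.spacing_um, obj.origin)
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:  # unwritable directory etc.
        raise OSError(f"cannot write MetaImage to {path}: {exc}") from exc
    return path


def read_metaimage(path: str | Path, as_mask: bool = False) -> OCTVolume | LabelMask:
    """Read a MetaImage file into an :class:`OCTVolume` (or :class:`LabelMask`).

    Spacing is taken from the header (``ElementSpacing``, mm) and converted
    to μm; index order is normalised to (b, z, x). 8/16-bit integer data are
    rescaled to [0, 1] for volumes; ``as_mask=True`` keeps integer labels.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such MetaImage file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise ValueError(f"unreadable MetaImage {path} (ElementType/ObjectType?): {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"NDims must be 3, got NDims={img.GetDimension()} in {path}")
    arr = sitk.GetArrayFromImage(img)  # (b, z, x)
    sp_mm = img.GetSpacing()  # (lateral, axial, inter_slice)
    spacing_um = (sp_mm[2] * 1000.0, sp_mm[1] * 1000.0, sp_mm[0] * 1000.0)
    og_mm = img.GetOrigin()
    origin_um = (og_mm[2] * 1000.0, og_mm[1] * 1000.0, og_mm[0] * 1000.0)
    if as_mask:
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"mask ElementType must be integer, got {arr.dtype} in {path}")
        return LabelMask(arr.astype(np.uint8), spacing_um, origin_um)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        if info.max not in (255, 65535):
            raise ValueError(f"unsupported ElementType {arr.dtype} in {path}; expected 8/16-bit unsigned")
        arr = arr.astype(np.float64) / info.max
    else:
        arr = arr.astype(np.float64)
    return OCTVolume(arr, spacing_um, origin_um)
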