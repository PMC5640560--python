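"""Image containers and I/O.

Conventions
-----------
Volumes are numpy arrays indexed ``(ix, iy, iz)`` where *x* is the
patient's left-right axis, *y* the anteroposterior axis (planar and SPECT
projections integrate along *y*), and *z* the axial (cranio-caudal) axis.
Voxel indices are 0-based; the world coordinate of the *center* of voxel
``i`` is ``origin + (i + 0.5) * spacing``.  Grids built by this package are
centered on the world origin.

Planar images are 2-D arrays indexed ``(ix, iz)``.

Volumes round-trip through SimpleITK, so ``.nii.gz``, ``.nii`` and ``.mha``
all work; SimpleITK stores arrays as (z, y, x), and the transpose is handled
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk


@dataclass
class ImageVolume:
    """A 3-D scalar grid with spacing (mm), origin (mm) and a unit label."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"ImageVolume expects a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"nonpositive spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in mL (1 mL = 1 cm^3 = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def with_data(self, data: np.ndarray, unit: str | None = None) -> "ImageVolume":
        return replace(self, data=data, unit=self.unit if unit is None else unit)

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm) of voxel centers along each axis."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )

    def total(self) -> float:
        return float(self.data.sum())


def centered_grid(shape: tuple[int, int, int], spacing_mm: float | tuple[float, float, float]):
    """Origin placing the grid symmetrically about the world origin."""
    if np.isscalar(spacing_mm):
        spacing = (float(spacing_mm),) * 3
    else:
        spacing = tuple(float(s) for s in spacing_mm)
    origin = tuple(-0.5 * n * s for n, s in zip(shape, spacing))
    return spacing, origin


def empty_volume(shape, spacing_mm, unit: str = "", dtype=float) -> ImageVolume:
    spacing, origin = centered_grid(tuple(shape), spacing_mm)
    return ImageVolume(np.zeros(shape, dtype=dtype), spacing, origin, unit)


@dataclass
class PlanarImage:
    """A 2-D planar scintigram indexed (ix, iz), pixel size in mm."""

    data: np.ndarray
    pixel_mm: tuple[float, float]
    unit: str = "counts"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"PlanarImage expects a 2-D array, got ndim={self.data.ndim}")
        self.pixel_mm = tuple(float(p) for p in self.pixel_mm)

    @property
    def shape(self):
        return self.data.shape

    def total(self) -> float:
        return float(self.data.sum())


def save_volume(vol: ImageVolume, path: str) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(o + 0.5 * s for o, s in zip(vol.origin, vol.spacing)))
    if vol.unit:
        img.SetMetaData("unit", vol.unit)
    sitk.WriteImage(img, path)


def load_volume(path: str) -> ImageVolume:
    img = sitk.ReadImage(path)
    data = sitk.GetArrayFromImage(img).T
    spacing = tuple(img.GetSpacing())
    origin = tuple(o - 0.5 * s for o, s in zip(img.GetOrigin(), spacing))
    unit = img.GetMetaData("unit") if img.HasMetaDataKey("unit") else ""
    return ImageVolume(data, spacing, origin, unit)


def save_planar(img: PlanarImage, path: str) -> None:
    s = sitk.GetImageFromArray(np.ascontiguousarray(img.data.T))
    s.SetSpacing(tuple(img.pixel_mm))
    if img.unit:
        s.SetMetaData("unit", img.unit)
    sitk.WriteImage(s, path)


def load_planar(path: str) -> PlanarImage:
    s = sitk.ReadImage(path)
    return PlanarImage(sitk.GetArrayFromImage(s).T, tuple(s.GetSpacing())[:2])
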