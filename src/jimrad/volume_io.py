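"""3D volume handling: NIfTI I/O, resampling, unit-range normalization and
fixed-size ROI extraction around tumor centroids.

Arrays are indexed ``(x, y, z)`` matching the NIfTI voxel axes returned by
nibabel. The processing order is fixed: resample the full volume to the
target spacing, min-max normalize the *whole* volume to [0, 1], then cut the
ROI window — so quantization bins downstream are shared across ROIs of the
same volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, OutOfBoundsError

__all__ = [
    "Volume3D",
    "ROISpec",
    "ROIVolume",
    "resample_volume",
    "normalize_unit_range",
    "extract_roi",
    "read_volume",
    "write_volume",
]

DEFAULT_WINDOW = (21, 21, 10)


@dataclass(frozen=True)
class Volume3D:
    """A scalar 3D image grid with physical voxel spacing (mm) and origin."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality_tag: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError(f"volume data must be 3D, got shape {data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class ROISpec:
    """Window of ``window`` voxels centered at a 0-based voxel index.

    For odd extents the window is symmetric, ``[c-(w-1)/2, c+(w-1)/2]``; for
    even extents it is half-open, ``[c-w/2, c+w/2)``. Both give a start index
    of ``c - w//2``.
    """

    centroid: tuple[int, int, int]
    window: tuple[int, int, int] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.window):
            raise ValueError(f"window extents must be >= 1, got {self.window}")

    def bounds(self) -> tuple[tuple[int, int], ...]:
        """Half-open index ranges (start, stop) along each axis."""
        return tuple(
            (c - w // 2, c - w // 2 + w) for c, w in zip(self.centroid, self.window)
        )


@dataclass(frozen=True)
class ROIVolume:
    """A sub-grid cut from a (normalized) volume; the unit of texture analysis."""

    data: np.ndarray
    source_modality: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"ROI data must be 3D, got shape {data.shape}")
        if self.normalized and (data.min() < 0.0 or data.max() > 1.0):
            raise ValueError("ROI flagged normalized but values fall outside [0, 1]")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def resample_volume(
    vol: Volume3D, target_spacing: tuple[float, float, float]
) -> Volume3D:
    """Trilinearly resample ``vol`` onto a grid with ``target_spacing`` (mm).

    The output grid has ``ceil(extent_mm / target_spacing)`` voxels per axis;
    sample locations are mapped into the source index space by the spacing
    ratio and interpolated with order-1 splines (trilinear). Resampling at the
    volume's own spacing is an exact no-op.
    """
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be > 0, got {target_spacing}")
    target_spacing = tuple(float(s) for s in target_spacing)
    extent = [n * s for n, s in zip(vol.shape, vol.spacing)]
    new_shape = tuple(
        int(np.ceil(e / t - 1e-9)) for e, t in zip(extent, target_spacing)
    )
    if new_shape == vol.shape and target_spacing == vol.spacing:
        return replace(vol, spacing=target_spacing)
    # sample point k on the new grid sits at index k * (target / source)
    grids = np.meshgrid(
        *[
            np.arange(n) * (t / s)
            for n, t, s in zip(new_shape, target_spacing, vol.spacing)
        ],
        indexing="ij",
    )
    data = ndimage.map_coordinates(
        vol.data, np.stack(grids), order=1, mode="nearest"
    )
    return replace(vol, data=data, spacing=target_spacing)


def normalize_unit_range(vol: Volume3D) -> Volume3D:
    """Affinely map intensities so the volume min is 0 and the max is 1."""
    lo, hi = float(vol.data.min()), float(vol.data.max())
    if hi == lo:
        raise DegenerateInputError(
            f"cannot normalize a constant volume (value {lo}); min equals max"
        )
    return replace(vol, data=(vol.data - lo) / (hi - lo))


def extract_roi(vol: Volume3D, spec: ROISpec) -> ROIVolume:
    """Cut the window described by ``spec`` out of ``vol``.

    Raises :class:`OutOfBoundsError` if the window does not fit — clipping or
    padding would inject artificial structure into co-occurrence counts.
    """
    slices = []
    for axis, ((start, stop), n) in enumerate(zip(spec.bounds(), vol.shape)):
        if start < 0 or stop > n:
            raise OutOfBoundsError(
                f"ROI window {spec.window} at centroid {spec.centroid} spans "
                f"[{start}, {stop}) on axis {axis}, outside volume of shape {vol.shape}"
            )
        slices.append(slice(start, stop))
    data = vol.data[tuple(slices)].copy()
    normalized = bool(data.min() >= 0.0 and data.max() <= 1.0)
    return ROIVolume(
        data=data, source_modality=vol.modality_tag, normalized=normalized
    )


def read_volume(path: str | Path, modality_tag: str = "") -> Volume3D:
    """Read a NIfTI-1 volume; spacing from the header zooms, origin from the
    affine translation."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed files surface the offending path
        raise ValueError(f"could not parse {path} as NIfTI: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim} dimensions"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume3D(data=data, spacing=spacing, origin=origin, modality_tag=modality_tag)


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write ``vol`` as NIfTI-1 with a diagonal affine built from spacing/origin."""
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
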