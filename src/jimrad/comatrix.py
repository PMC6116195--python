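"""Gray-level quantization and co-occurrence matrices.

The joint intensity matrix (JIM) counts, for a spatial displacement
``L(d, theta)``, how often level *i* in one modality co-occurs with level *j*
in a second co-registered modality at the displaced voxel:

    C(i, j) = #{ x in R : I1(x) = i  and  I2(L(x)) = j }

normalized to a probability distribution by the total pair count. The
classical GLCM is the special case I1 = I2. Matrices are directional (no
symmetrization): rows index the first modality, columns the second, so a JIM
is inherently asymmetric. The four angles are in-plane (axial); counts
accumulate across every slice of the 3D ROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateOffsetError
from .volume_io import ROIVolume

__all__ = [
    "QuantizedROI",
    "Offset",
    "CoMatrix",
    "quantize",
    "compute_jim",
    "compute_glcm",
    "comatrix_bank",
    "default_offsets",
    "DEFAULT_LEVELS",
    "DEFAULT_DISTANCES",
    "DEFAULT_ANGLES",
]

DEFAULT_LEVELS = (8, 16, 32, 64, 128)
DEFAULT_DISTANCES = (1, 2, 3, 4)
DEFAULT_ANGLES = (0, 45, 90, 135)

# In-plane displacement per angle, in (x, y, z) index steps for distance d.
# Diagonals use unnormalized (d, d) steps (Chebyshev distance d), the classic
# Haralick convention.
_ANGLE_STEPS = {0: (1, 0, 0), 45: (1, -1, 0), 90: (0, -1, 0), 135: (-1, -1, 0)}


@dataclass(frozen=True)
class QuantizedROI:
    """Integer-level ROI with voxel values in {1, ..., n_levels}."""

    levels: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels)
        if levels.ndim != 3:
            raise ValueError(f"quantized ROI must be 3D, got shape {levels.shape}")
        if self.n_levels < 1:
            raise ValueError(f"n_levels must be >= 1, got {self.n_levels}")
        if levels.min() < 1 or levels.max() > self.n_levels:
            raise ValueError(
                f"levels must lie in [1, {self.n_levels}], "
                f"got range [{levels.min()}, {levels.max()}]"
            )
        object.__setattr__(self, "levels", levels.astype(np.int64))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.levels.shape


@dataclass(frozen=True)
class Offset:
    """Co-occurrence displacement: distance ``d`` voxels at one of the four
    in-plane angles 0/45/90/135 degrees."""

    distance: int
    angle: int

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError(f"distance must be >= 1, got {self.distance}")
        if self.angle not in _ANGLE_STEPS:
            raise ValueError(
                f"angle must be one of {sorted(_ANGLE_STEPS)}, got {self.angle}"
            )

    @property
    def displacement(self) -> tuple[int, int, int]:
        step = _ANGLE_STEPS[self.angle]
        return tuple(self.distance * s for s in step)


def default_offsets(
    distances: Sequence[int] = DEFAULT_DISTANCES,
    angles: Sequence[int] = DEFAULT_ANGLES,
) -> list[Offset]:
    """The default 16 offsets: distance-major, then angle."""
    return [Offset(d, a) for d in distances for a in angles]


@dataclass(frozen=True)
class CoMatrix:
    """An N x N co-occurrence probability matrix with its provenance."""

    probs: np.ndarray
    n_levels: int
    offset: Offset
    kind: str  # "JIM" or "GLCM"
    source: tuple[str, str]
    pair_count: int

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        if probs.shape != (self.n_levels, self.n_levels):
            raise ValueError(
                f"probs must be {self.n_levels}x{self.n_levels}, got {probs.shape}"
            )
        if probs.min() < 0:
            raise ValueError("co-occurrence probabilities must be non-negative")
        object.__setattr__(self, "probs", probs)

    @property
    def counts(self) -> np.ndarray:
        return self.probs * self.pair_count


def quantize(roi: ROIVolume, n_levels: int) -> QuantizedROI:
    """Quantize a [0, 1]-normalized ROI onto ``n_levels`` uniform bins.

    ``level(v) = min(floor(v * N) + 1, N)``: bins are fixed on the global
    [0, 1] range (no per-ROI re-stretching) and the top bin is closed so
    v = 1.0 maps to level N.
    """
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    data = roi.data
    if data.min() < 0.0 or data.max() > 1.0:
        raise ValueError(
            "ROI values must lie in [0, 1]; normalize the volume before quantizing"
        )
    levels = np.minimum(np.floor(data * n_levels).astype(np.int64) + 1, n_levels)
    return QuantizedROI(levels=levels, n_levels=n_levels)


def _shift_slices(shape: tuple[int, ...], disp: tuple[int, ...]):
    """Index slices (anchor, displaced) so displaced = anchor + disp stays
    in bounds."""
    anchor, displaced = [], []
    for n, d in zip(shape, disp):
        if abs(d) >= n:
            return None
        if d >= 0:
            anchor.append(slice(0, n - d))
            displaced.append(slice(d, n))
        else:
            anchor.append(slice(-d, n))
            displaced.append(slice(0, n + d))
    return tuple(anchor), tuple(displaced)


def compute_jim(q1: QuantizedROI, q2: QuantizedROI, offset: Offset) -> CoMatrix:
    """Joint intensity matrix of two co-registered quantized ROIs.

    Every voxel x with x + displacement inside the ROI contributes one count
    to cell ``(q1(x), q2(x + displacement))``; counts are normalized by the
    total pair count.
    """
    if q1.shape != q2.shape:
        raise ValueError(f"ROI shapes differ: {q1.shape} vs {q2.shape}")
    if q1.n_levels != q2.n_levels:
        raise ValueError(
            f"quantization levels differ: {q1.n_levels} vs {q2.n_levels}"
        )
    n = q1.n_levels
    sl = _shift_slices(q1.shape, offset.displacement)
    if sl is None:
        raise DegenerateOffsetError(
            f"displacement {offset.displacement} leaves no voxel pairs in an ROI "
            f"of shape {q1.shape}"
        )
    anchor, displaced = sl
    i = q1.levels[anchor].ravel() - 1
    j = q2.levels[displaced].ravel() - 1
    if i.size == 0:
        raise DegenerateOffsetError(
            f"displacement {offset.displacement} leaves no voxel pairs in an ROI "
            f"of shape {q1.shape}"
        )
    counts = np.bincount(i * n + j, minlength=n * n).reshape(n, n).astype(np.float64)
    pair_count = int(i.size)
    kind = "GLCM" if q1 is q2 else "JIM"
    return CoMatrix(
        probs=counts / pair_count,
        n_levels=n,
        offset=offset,
        kind=kind,
        source=("I1", "I2") if kind == "JIM" else ("I1", "I1"),
        pair_count=pair_count,
    )


def compute_glcm(q: QuantizedROI, offset: Offset) -> CoMatrix:
    """Gray-level co-occurrence matrix: the JIM of an ROI with itself."""
    return compute_jim(q, q, offset)


def comatrix_bank(
    roi1: ROIVolume,
    roi2: ROIVolume | None = None,
    levels: Iterable[int] = DEFAULT_LEVELS,
    offsets: Sequence[Offset] | None = None,
    source: tuple[str, str] | None = None,
) -> list[CoMatrix]:
    """All co-occurrence matrices for a level set x offset set.

    One ROI gives a GLCM bank, two give a JIM bank. Each level re-quantizes
    the stored continuous ROI (never merges a finer quantization). Order is
    deterministic: level-major, then distance, then angle — 5 x 4 x 4 = 80
    matrices by default.
    """
    levels = list(levels)
    offsets = list(offsets) if offsets is not None else default_offsets()
    if not levels or not offsets:
        raise ValueError("level and offset sets must be non-empty")
    out: list[CoMatrix] = []
    for n in levels:
        q1 = quantize(roi1, n)
        q2 = q1 if roi2 is None else quantize(roi2, n)
        for off in offsets:
            m = compute_jim(q1, q2, off)
            if source is not None:
                m = CoMatrix(
                    probs=m.probs,
                    n_levels=m.n_levels,
                    offset=m.offset,
                    kind=m.kind,
                    source=source,
                    pair_count=m.pair_count,
                )
            out.append(m)
    return out
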