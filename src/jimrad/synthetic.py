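"""Synthetic paired-modality phantoms and labeled cohorts.

Real study data (co-registered T2-weighted and ADC prostate MRI with
biopsy-graded tumors) cannot ship with the package, so this module builds
statistically controllable stand-ins. Each case is a pair of 3D ROIs derived
from a shared latent texture field:

    latent  = white noise smoothed by a Gaussian kernel (correlation length
              ``corr_length`` voxels)
    A       = latent + eps_A                      (pseudo T2-WI)
    B       = rho * latent + sqrt(1 - rho^2) * latent' + eps_B   (pseudo ADC)

where ``latent'`` is an independent field with the same spectrum and the
eps are white noise of standard deviation ``noise_sd`` (in units of the
latent field's SD). Both volumes are min-max normalized to [0, 1]. ``rho``
sets the cross-modality coupling that the joint intensity matrix reads out.

Group structure: the effect scalar ``delta`` scales the latent correlation
length per Gleason grouping (G2 coarser texture, G3 finer, G1 baseline), so
second-order co-occurrence features — contrast, difference variance —
separate the groups while first-order histograms barely move (texture grain
changes, the marginal intensity distribution does not). Group sizes default
to 30/39/30.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import ROIVolume, Volume3D, write_volume

__all__ = [
    "PhantomParams",
    "SyntheticCase",
    "SyntheticCohort",
    "generate_pair",
    "generate_cohort",
    "write_cohort",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_EFFECT",
]

DEFAULT_GROUP_SIZES = (30, 39, 30)
DEFAULT_EFFECT = 0.3

#: correlation-length exponent per group at effect scalar delta: G2 gets a
#: coarser latent field ((1+delta)x), G3 finer (1/(1+delta)), G1 baseline.
#: A coarser latent field spans a narrower share of the [0,1] range after
#: min-max normalization, so the additive noise occupies proportionally more
#: of it and co-occurrence contrast rises: contrast orders G2 > G1 > G3.
_GROUP_SCALE = {"G1": 0.0, "G2": 1.0, "G3": -1.0}


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for one paired-modality phantom ROI."""

    shape: tuple[int, int, int] = (21, 21, 10)
    corr_length: float = 2.0
    rho: float = 0.6
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be positive, got {self.shape}")


@dataclass(frozen=True)
class SyntheticCase:
    case_id: str
    t2: ROIVolume
    adc: ROIVolume
    group: str


@dataclass(frozen=True)
class SyntheticCohort:
    cases: list[SyntheticCase]
    manifest: dict  # generation parameters + seed, for reproducibility

    def __len__(self) -> int:
        return len(self.cases)

    def group_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.cases:
            out[c.group] = out.get(c.group, 0) + 1
        return out


def _smooth_field(rng: np.random.Generator, shape, corr_length: float) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    field = rng.standard_normal(shape)
    if corr_length > 0:
        field = ndimage.gaussian_filter(field, sigma=corr_length, mode="wrap")
    sd = field.std()
    if sd > 0:
        field = field / sd
    return field


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def generate_pair(params: PhantomParams) -> tuple[ROIVolume, ROIVolume]:
    """One co-registered pseudo-T2 / pseudo-ADC ROI pair.

    With ``rho = 1`` and zero noise the two volumes are identical after
    normalization; with ``rho = 0`` they are voxel-wise independent.
    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    latent = _smooth_field(rng, params.shape, params.corr_length)
    latent_indep = _smooth_field(rng, params.shape, params.corr_length)
    a = latent + params.noise_sd * rng.standard_normal(params.shape)
    b = (
        params.rho * latent
        + np.sqrt(1.0 - params.rho**2) * latent_indep
        + params.noise_sd * rng.standard_normal(params.shape)
    )
    t2 = ROIVolume(data=_minmax(a), source_modality="T2-WI", normalized=True)
    adc = ROIVolume(data=_minmax(b), source_modality="ADC", normalized=True)
    return t2, adc


def _group_params(base: PhantomParams, group: str, delta: float) -> PhantomParams:
    scale = (1.0 + delta) ** _GROUP_SCALE[group]
    return replace(base, corr_length=base.corr_length * scale)


def generate_cohort(
    n_per_group: tuple[int, int, int] = DEFAULT_GROUP_SIZES,
    effect: float = DEFAULT_EFFECT,
    seed: int = 0,
    base_params: PhantomParams | None = None,
) -> SyntheticCohort:
    """A labeled cohort of paired phantoms with group-dependent texture.

    ``effect = 0`` gives an exchangeable null cohort (every group drawn from
    the same distribution); larger values increase the texture-grain
    separation between groups monotonically.
    """
    if any(n < 1 for n in n_per_group):
        raise ValueError(f"group sizes must be >= 1, got {n_per_group}")
    if effect < 0:
        raise ValueError(f"effect must be >= 0, got {effect}")
    base = base_params if base_params is not None else PhantomParams(seed=seed)
    rng = np.random.default_rng(seed)
    cases: list[SyntheticCase] = []
    for group, n in zip(("G1", "G2", "G3"), n_per_group):
        for k in range(n):
            case_seed = int(rng.integers(0, 2**31 - 1))
            params = replace(
                _group_params(base, group, effect), seed=case_seed
            )
            t2, adc = generate_pair(params)
            cases.append(
                SyntheticCase(
                    case_id=f"{group}_{k:03d}", t2=t2, adc=adc, group=group
                )
            )
    manifest = {
        "n_per_group": list(n_per_group),
        "effect": effect,
        "seed": seed,
        "shape": list(base.shape),
        "corr_length": base.corr_length,
        "rho": base.rho,
        "noise_sd": base.noise_sd,
    }
    return SyntheticCohort(cases=cases, manifest=manifest)


def write_cohort(
    cohort: SyntheticCohort,
    out_dir: str | Path,
    volume_shape: tuple[int, int, int] | None = None,
    background_sd: float = 0.05,
) -> Path:
    """Write a cohort as NIfTI volumes plus the centroid/label manifest CSV.

    Each ROI is embedded at the center of a larger background volume (mild
    Gaussian noise around 0.5) so the synthetic path exercises the same ROI
    extraction code as real data. Returns the manifest path; the CSV columns
    are ``case_id, modality_t2_path, modality_adc_path, cx, cy, cz,
    gleason_group`` with 0-based centroid indices.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(int(cohort.manifest.get("seed", 0)) + 7)
    rows = []
    for case in cohort.cases:
        roi_shape = case.t2.shape
        vol_shape = volume_shape or tuple(s + 20 for s in roi_shape)
        if any(v < r for v, r in zip(vol_shape, roi_shape)):
            raise ValueError(
                f"volume shape {vol_shape} smaller than ROI shape {roi_shape}"
            )
        centroid = tuple(v // 2 for v in vol_shape)
        starts = [c - r // 2 for c, r in zip(centroid, roi_shape)]
        paths = {}
        for tag, roi in (("t2", case.t2), ("adc", case.adc)):
            bg = np.clip(
                0.5 + background_sd * rng.standard_normal(vol_shape), 0.0, 1.0
            )
            sl = tuple(
                slice(s, s + r) for s, r in zip(starts, roi_shape)
            )
            bg[sl] = roi.data
            # force the volume to span [0,1] so a later whole-volume
            # normalization leaves the ROI values untouched
            bg.flat[0], bg.flat[1] = 0.0, 1.0
            vol = Volume3D(
                data=bg, modality_tag="T2-WI" if tag == "t2" else "ADC"
            )
            path = out_dir / f"{case.case_id}_{tag}.nii"
            write_volume(vol, path)
            paths[tag] = path.name
        rows.append(
            (
                case.case_id,
                paths["t2"],
                paths["adc"],
                *centroid,
                case.group,
            )
        )
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "case_id",
                "modality_t2_path",
                "modality_adc_path",
                "cx",
                "cy",
                "cz",
                "gleason_group",
            ]
        )
        writer.writerows(rows)
    return manifest_path
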