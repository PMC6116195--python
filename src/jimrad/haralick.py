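"""Haralick quantifier functions, bank aggregation, the 57-feature tumor
signature, and first-order histogram features.

Each co-occurrence matrix is summarized by 19 scalar functions of its joint
probability table p(i, j), i, j in {1..N} (level labels, so distance-weighted
features are in level units). A tumor's texture signature is the per-function
average over the full bank of matrices (5 quantization levels x 4 distances x
4 angles = 80 by default), computed three times: GLCM of the T2-weighted ROI,
GLCM of the ADC ROI, and the cross-modality JIM — 57 named features.

Conventions fixed here: logarithms are base 2 with 0*log 0 := 0; correlation
is 0 when either marginal SD is 0; information correlation 1 is 0 when
max(HX, HY) = 0; information correlation 2 is clipped below at 0; sum
variance is centered on sum average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .comatrix import CoMatrix, comatrix_bank, default_offsets, DEFAULT_LEVELS
from .errors import DegenerateInputError
from .volume_io import ROIVolume

__all__ = [
    "FEATURE_NAMES",
    "MATRIX_TAGS",
    "MarginalSet",
    "marginals",
    "haralick19",
    "aggregate_bank",
    "tumor_signature",
    "signature_feature_names",
    "histogram_features",
    "HISTOGRAM_FEATURE_NAMES",
]

FEATURE_NAMES = (
    "angular_second_moment",
    "contrast",
    "correlation",
    "sum_of_squares_variance",
    "homogeneity",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "information_correlation_1",
    "information_correlation_2",
    "autocorrelation",
    "dissimilarity",
    "cluster_shade",
    "cluster_prominence",
    "maximum_probability",
    "inverse_difference",
)

#: the three matrix blocks of the tumor signature, in column order
MATRIX_TAGS = ("GLCM_T2", "GLCM_ADC", "JIM")

HISTOGRAM_FEATURE_NAMES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
)


def _entropy2(p: np.ndarray) -> float:
    """Shannon entropy in bits with the 0*log 0 := 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


@dataclass(frozen=True)
class MarginalSet:
    """Marginal distributions and entropies of a co-occurrence matrix."""

    p_x: np.ndarray  # row marginal, index i = 1..N
    p_y: np.ndarray  # column marginal, index j = 1..N
    p_sum: np.ndarray  # p_{x+y}(k), k = 2..2N
    p_diff: np.ndarray  # p_{x-y}(k), k = 0..N-1
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    hx: float
    hy: float
    hxy: float
    hxy1: float
    hxy2: float


def marginals(m: CoMatrix) -> MarginalSet:
    """Row/column, sum and absolute-difference marginals plus the entropy
    quantities entering the information-correlation features."""
    p = m.probs
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(
            f"matrix must be normalized to unit mass, sums to {total:.6g}"
        )
    n = m.n_levels
    p_x = p.sum(axis=1)
    p_y = p.sum(axis=0)
    idx = np.arange(1, n + 1, dtype=np.float64)
    mu_x = float(idx @ p_x)
    mu_y = float(idx @ p_y)
    sigma_x = float(np.sqrt(((idx - mu_x) ** 2) @ p_x))
    sigma_y = float(np.sqrt(((idx - mu_y) ** 2) @ p_y))

    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    p_sum = np.bincount((i + j).ravel(), weights=p.ravel(), minlength=2 * n - 1)
    p_diff = np.bincount(np.abs(i - j).ravel(), weights=p.ravel(), minlength=n)

    px_py = np.outer(p_x, p_y)
    pos = p > 0
    hxy1 = float(-(p[pos] * np.log2(px_py[pos])).sum()) if pos.any() else 0.0
    return MarginalSet(
        p_x=p_x,
        p_y=p_y,
        p_sum=p_sum,
        p_diff=p_diff,
        mu_x=mu_x,
        mu_y=mu_y,
        sigma_x=sigma_x,
        sigma_y=sigma_y,
        hx=_entropy2(p_x),
        hy=_entropy2(p_y),
        hxy=_entropy2(p.ravel()),
        hxy1=hxy1,
        hxy2=_entropy2(px_py.ravel()),
    )


def haralick19(m: CoMatrix) -> dict[str, float]:
    """The 19 Haralick quantifiers of one normalized co-occurrence matrix."""
    p = m.probs
    if p.sum() <= 0:
        raise DegenerateInputError("cannot quantify an all-zero matrix")
    n = m.n_levels
    mg = marginals(m)
    idx = np.arange(1, n + 1, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    diff2 = (i - j) ** 2
    absdiff = np.abs(i - j)

    k_sum = np.arange(2, 2 * n + 1, dtype=np.float64)  # support of p_{x+y}
    k_diff = np.arange(0, n, dtype=np.float64)  # support of p_{x-y}
    sum_avg = float(k_sum @ mg.p_sum)
    mu_d = float(k_diff @ mg.p_diff)

    if mg.sigma_x > 0 and mg.sigma_y > 0:
        correlation = float(
            ((i * j * p).sum() - mg.mu_x * mg.mu_y) / (mg.sigma_x * mg.sigma_y)
        )
    else:
        correlation = 0.0
    denom = max(mg.hx, mg.hy)
    info1 = (mg.hxy - mg.hxy1) / denom if denom > 0 else 0.0
    info2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (mg.hxy2 - mg.hxy)))))

    cluster = i + j - mg.mu_x - mg.mu_y
    return {
        "angular_second_moment": float((p**2).sum()),
        "contrast": float((diff2 * p).sum()),
        "correlation": correlation,
        "sum_of_squares_variance": float((((i - mg.mu_x) ** 2) * p).sum()),
        "homogeneity": float((p / (1.0 + diff2)).sum()),
        "sum_average": sum_avg,
        "sum_variance": float(((k_sum - sum_avg) ** 2) @ mg.p_sum),
        "sum_entropy": _entropy2(mg.p_sum),
        "entropy": mg.hxy,
        "difference_variance": float(((k_diff - mu_d) ** 2) @ mg.p_diff),
        "difference_entropy": _entropy2(mg.p_diff),
        "information_correlation_1": float(info1),
        "information_correlation_2": info2,
        "autocorrelation": float((i * j * p).sum()),
        "dissimilarity": float((absdiff * p).sum()),
        "cluster_shade": float((cluster**3 * p).sum()),
        "cluster_prominence": float((cluster**4 * p).sum()),
        "maximum_probability": float(p.max()),
        "inverse_difference": float((p / (1.0 + absdiff)).sum()),
    }


def aggregate_bank(bank: list[CoMatrix]) -> dict[str, float]:
    """Unweighted mean of each quantifier over a bank of matrices.

    All matrices must share kind and source: averaging mixes quantization
    levels, distances and angles of one matrix family, never families.
    """
    if not bank:
        raise ValueError("bank must be non-empty")
    kinds = {m.kind for m in bank}
    sources = {m.source for m in bank}
    if len(kinds) > 1 or len(sources) > 1:
        raise ValueError(
            f"bank mixes matrix families: kinds {kinds}, sources {sources}"
        )
    acc = {name: 0.0 for name in FEATURE_NAMES}
    for m in bank:
        for name, value in haralick19(m).items():
            acc[name] += value
    return {name: value / len(bank) for name, value in acc.items()}


def signature_feature_names() -> list[str]:
    """Column order of the 57-feature signature: GLCM_T2, GLCM_ADC, JIM blocks."""
    return [f"{tag}_{name}" for tag in MATRIX_TAGS for name in FEATURE_NAMES]


def tumor_signature(
    t2_roi: ROIVolume,
    adc_roi: ROIVolume,
    levels=DEFAULT_LEVELS,
    distances=None,
    angles=None,
) -> dict[str, float]:
    """The 57-feature texture signature of one tumor.

    19 bank-averaged quantifiers for each of GLCM(T2), GLCM(ADC) and the
    cross-modality JIM with T2 on rows and ADC on columns. A pure function of
    its inputs.
    """
    if t2_roi.shape != adc_roi.shape:
        raise ValueError(
            f"ROI shapes differ: {t2_roi.shape} vs {adc_roi.shape}"
        )
    kwargs = {}
    if distances is not None or angles is not None:
        from .comatrix import DEFAULT_ANGLES, DEFAULT_DISTANCES

        kwargs["offsets"] = default_offsets(
            distances or DEFAULT_DISTANCES, angles or DEFAULT_ANGLES
        )
    blocks = {
        "GLCM_T2": aggregate_bank(
            comatrix_bank(t2_roi, levels=levels, source=("T2", "T2"), **kwargs)
        ),
        "GLCM_ADC": aggregate_bank(
            comatrix_bank(adc_roi, levels=levels, source=("ADC", "ADC"), **kwargs)
        ),
        "JIM": aggregate_bank(
            comatrix_bank(
                t2_roi, adc_roi, levels=levels, source=("T2", "ADC"), **kwargs
            )
        ),
    }
    return {
        f"{tag}_{name}": blocks[tag][name]
        for tag in MATRIX_TAGS
        for name in FEATURE_NAMES
    }


def histogram_features(roi: ROIVolume, n_bins: int = 64) -> dict[str, float]:
    """First-order features of one ROI.

    Moment statistics (mean, population variance, Fisher skewness, Pearson
    kurtosis) are computed from the raw voxel values; energy and entropy from
    an ``n_bins``-bin normalized histogram on [0, 1].
    """
    v = roi.data.ravel()
    if v.size == 0:
        raise DegenerateInputError("ROI is empty")
    mean = float(v.mean())
    var = float(v.var())
    if var > 0:
        sd = np.sqrt(var)
        skew = float(((v - mean) ** 3).mean() / sd**3)
        kurt = float(((v - mean) ** 4).mean() / sd**4)
    else:
        skew, kurt = 0.0, 0.0
    counts, _ = np.histogram(v, bins=n_bins, range=(0.0, 1.0))
    q = counts / counts.sum()
    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((q**2).sum()),
        "entropy": _entropy2(q),
    }
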