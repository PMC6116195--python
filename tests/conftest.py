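"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (explicit Python loops, literal
formula transcriptions) and share no code with the package implementation:
they exist to check the vectorized code paths against first principles.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

from jimrad import CohortTable, PhantomParams, ROIVolume, generate_pair


def cooccurrence_oracle(lv1: np.ndarray, lv2: np.ndarray, disp, n: int) -> np.ndarray:
    """Brute-force pair enumeration: count (i at x, j at x+disp) over all
    voxels whose displaced partner stays inside the grid."""
    counts = np.zeros((n, n))
    nx, ny, nz = lv1.shape
    dx, dy, dz = disp
    for x, y, z in product(range(nx), range(ny), range(nz)):
        x2, y2, z2 = x + dx, y + dy, z + dz
        if 0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz:
            counts[lv1[x, y, z] - 1, lv2[x2, y2, z2] - 1] += 1
    return counts


def _log2(v: float) -> float:
    return math.log2(v) if v > 0 else 0.0


def haralick_oracle(p: np.ndarray) -> dict[str, float]:
    """Literal double-loop transcription of the 19 quantifier formulas."""
    n = p.shape[0]
    px = [sum(p[i, j] for j in range(n)) for i in range(n)]
    py = [sum(p[i, j] for i in range(n)) for j in range(n)]
    mux = sum((i + 1) * px[i] for i in range(n))
    muy = sum((j + 1) * py[j] for j in range(n))
    sx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(n)))
    sy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(n)))
    psum = {k: 0.0 for k in range(2, 2 * n + 1)}
    pdiff = {k: 0.0 for k in range(0, n)}
    for i in range(n):
        for j in range(n):
            psum[i + j + 2] += p[i, j]
            pdiff[abs(i - j)] += p[i, j]
    sa = sum(k * v for k, v in psum.items())
    mud = sum(k * v for k, v in pdiff.items())
    hx = -sum(v * _log2(v) for v in px)
    hy = -sum(v * _log2(v) for v in py)
    hxy = -sum(p[i, j] * _log2(p[i, j]) for i in range(n) for j in range(n))
    hxy1 = -sum(
        p[i, j] * _log2(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if p[i, j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * _log2(px[i] * py[j]) for i in range(n) for j in range(n)
    )
    corr = 0.0
    if sx > 0 and sy > 0:
        corr = (
            sum((i + 1) * (j + 1) * p[i, j] for i in range(n) for j in range(n))
            - mux * muy
        ) / (sx * sy)
    denom = max(hx, hy)
    return {
        "angular_second_moment": sum(
            p[i, j] ** 2 for i in range(n) for j in range(n)
        ),
        "contrast": sum(
            (i - j) ** 2 * p[i, j] for i in range(n) for j in range(n)
        ),
        "correlation": corr,
        "sum_of_squares_variance": sum(
            (i + 1 - mux) ** 2 * p[i, j] for i in range(n) for j in range(n)
        ),
        "homogeneity": sum(
            p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n)
        ),
        "sum_average": sa,
        "sum_variance": sum((k - sa) ** 2 * v for k, v in psum.items()),
        "sum_entropy": -sum(v * _log2(v) for v in psum.values()),
        "entropy": hxy,
        "difference_variance": sum((k - mud) ** 2 * v for k, v in pdiff.items()),
        "difference_entropy": -sum(v * _log2(v) for v in pdiff.values()),
        "information_correlation_1": (hxy - hxy1) / denom if denom > 0 else 0.0,
        "information_correlation_2": math.sqrt(
            max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))
        ),
        "autocorrelation": sum(
            (i + 1) * (j + 1) * p[i, j] for i in range(n) for j in range(n)
        ),
        "dissimilarity": sum(
            abs(i - j) * p[i, j] for i in range(n) for j in range(n)
        ),
        "cluster_shade": sum(
            (i + j + 2 - mux - muy) ** 3 * p[i, j]
            for i in range(n)
            for j in range(n)
        ),
        "cluster_prominence": sum(
            (i + j + 2 - mux - muy) ** 4 * p[i, j]
            for i in range(n)
            for j in range(n)
        ),
        "maximum_probability": max(p[i, j] for i in range(n) for j in range(n)),
        "inverse_difference": sum(
            p[i, j] / (1 + abs(i - j)) for i in range(n) for j in range(n)
        ),
    }


def ranksum_enumeration(a, b) -> tuple[float, float]:
    """Exact two-sided rank-sum test by enumerating every assignment of the
    pooled (tie-free) sample to the first group."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: r for r, v in enumerate(pooled, start=1)}
    w_obs = sum(ranks[v] for v in a)
    n1 = len(a)
    stats = [
        sum(pos + 1 for pos in combo)
        for combo in combinations(range(len(pooled)), n1)
    ]
    mean_w = sum(stats) / len(stats)
    extreme = sum(
        1 for w in stats if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12
    )
    return float(w_obs), extreme / len(stats)


def random_comatrix(rng: np.random.Generator, n: int):
    """A random normalized co-occurrence matrix wrapped as CoMatrix."""
    from jimrad import CoMatrix, Offset

    raw = rng.random((n, n))
    raw[rng.random((n, n)) < 0.2] = 0.0  # exercise the 0*log0 branches
    if raw.sum() == 0:
        raw[0, 0] = 1.0
    return CoMatrix(
        probs=raw / raw.sum(),
        n_levels=n,
        offset=Offset(1, 0),
        kind="GLCM",
        source=("I1", "I1"),
        pair_count=1000,
    )


def make_feature_cohort(
    rng: np.random.Generator,
    n_per_group=(30, 39, 30),
    n_features: int = 57,
    planted: dict[int, float] | None = None,
    planted_group: str = "G1",
) -> CohortTable:
    """Gaussian-noise feature cohort with optional planted group shifts.

    ``planted`` maps feature index -> mean shift added to cases of
    ``planted_group`` on that feature.
    """
    groups = np.repeat(["G1", "G2", "G3"], n_per_group)
    X = rng.standard_normal((len(groups), n_features))
    if planted:
        mask = groups == planted_group
        for f_idx, shift in planted.items():
            X[mask, f_idx] += shift
    ids = [f"case_{k:03d}" for k in range(len(groups))]
    return CohortTable(
        features=pd.DataFrame(
            X, index=ids, columns=[f"f{k:02d}" for k in range(n_features)]
        ),
        groups=pd.Series(groups, index=ids),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture
def small_roi_pair() -> tuple[ROIVolume, ROIVolume]:
    """A fixed 11x11x6 phantom pair, small enough for fast bank computation."""
    return generate_pair(PhantomParams(shape=(11, 11, 6), seed=42))
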