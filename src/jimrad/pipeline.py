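"""End-to-end workflow steps: manifest -> feature table -> univariate
screen -> classifier summaries.

Each step is a plain function over DataFrames so it is usable from Python;
the command-line front end in :mod:`jimrad.cli` only parses arguments and
calls these.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import SplitSpec, default_feature_subsets, run_all_tasks, train_eval_rf, balanced_split
from .config import RunConfig
from .haralick import (
    HISTOGRAM_FEATURE_NAMES,
    histogram_features,
    signature_feature_names,
    tumor_signature,
)
from .stats import CohortTable, univariate_screen
from .volume_io import ROISpec, extract_roi, normalize_unit_range, read_volume, resample_volume

logger = logging.getLogger("jimrad")

__all__ = [
    "read_manifest",
    "extract_case_features",
    "extract_features",
    "analyze_features",
    "classify_features",
]

MANIFEST_COLUMNS = [
    "case_id",
    "modality_t2_path",
    "modality_adc_path",
    "cx",
    "cy",
    "cz",
    "gleason_group",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate the centroid/label manifest CSV."""
    path = Path(path)
    manifest = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    if len(manifest) == 0:
        raise ValueError(f"{path}: manifest is empty")
    return manifest


def _load_roi(vol_path: Path, centroid, config: RunConfig, tag: str):
    vol = read_volume(vol_path, modality_tag=tag)
    if config.resample:
        vol = resample_volume(vol, config.target_spacing)
    vol = normalize_unit_range(vol)
    spec = ROISpec(centroid=tuple(int(c) for c in centroid), window=config.roi_window)
    return extract_roi(vol, spec)


def extract_case_features(
    row: pd.Series, base_dir: Path, config: RunConfig
) -> dict[str, float]:
    """All 57 texture + 12 histogram features for one manifest row."""
    centroid = (row["cx"], row["cy"], row["cz"])
    t2 = _load_roi(base_dir / row["modality_t2_path"], centroid, config, "T2-WI")
    adc = _load_roi(base_dir / row["modality_adc_path"], centroid, config, "ADC")
    feats = tumor_signature(
        t2, adc, levels=config.levels,
        distances=config.distances, angles=config.angles,
    )
    for tag, roi in (("T2", t2), ("ADC", adc)):
        for name, value in histogram_features(roi, n_bins=config.histogram_bins).items():
            feats[f"HIST_{tag}_{name}"] = value
    return feats


def extract_features(
    manifest_path: str | Path,
    config: RunConfig = RunConfig(),
    skip_errors: bool = False,
) -> pd.DataFrame:
    """Feature table for every case in a manifest: one row per case with the
    57 texture and 12 histogram features plus the ``gleason_group`` label."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base_dir = manifest_path.parent
    rows, index = [], []
    for _, row in manifest.iterrows():
        try:
            feats = extract_case_features(row, base_dir, config)
        except Exception:
            logger.exception("feature extraction failed for case %s", row["case_id"])
            if skip_errors:
                continue
            raise
        feats["gleason_group"] = row["gleason_group"]
        rows.append(feats)
        index.append(row["case_id"])
    if not rows:
        raise ValueError("no case produced features")
    table = pd.DataFrame(rows, index=pd.Index(index, name="case_id"))
    expected = signature_feature_names() + [
        f"HIST_{tag}_{n}" for tag in ("T2", "ADC") for n in HISTOGRAM_FEATURE_NAMES
    ]
    return table[expected + ["gleason_group"]]


def analyze_features(
    features: pd.DataFrame,
    config: RunConfig = RunConfig(),
    family: str = "texture",
) -> pd.DataFrame:
    """Univariate screen of a feature table.

    ``family`` selects the correction family: "texture" (the 57 signature
    columns, the default protocol), "histogram" (the 12 first-order
    columns), or "all".
    """
    cohort = CohortTable.from_frame(features)
    if family == "texture":
        cols = [c for c in cohort.features.columns if not c.startswith("HIST_")]
    elif family == "histogram":
        cols = [c for c in cohort.features.columns if c.startswith("HIST_")]
    elif family == "all":
        cols = list(cohort.features.columns)
    else:
        raise ValueError(f"unknown family {family!r}")
    if not cols:
        raise ValueError(f"no features for family {family!r}")
    sub = CohortTable(cohort.features[cols], cohort.groups)
    result = univariate_screen(sub, alpha=config.alpha)
    out = result.table.copy()
    out["m"] = result.m
    out["neg_log10_p"] = -np.log10(out["kw_p"].clip(lower=1e-300))
    return out


def classify_features(
    features: pd.DataFrame,
    config: RunConfig = RunConfig(),
    n_reps: int | None = None,
    with_importance: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-vs-all forest AUCs per feature subset, plus OOB permutation
    importance of the combined signature on the first split of each task.

    Returns ``(auc_table, importance_table)``.
    """
    cohort = CohortTable.from_frame(features)
    spec = SplitSpec(
        n_train_pos=config.n_train_pos,
        n_train_neg=config.n_train_neg,
        n_test_pos=config.n_test_pos,
        n_test_neg=config.n_test_neg,
    )
    reps = n_reps if n_reps is not None else config.n_reps
    auc = run_all_tasks(
        cohort,
        spec=spec,
        n_trees=config.n_trees,
        n_reps=reps,
        seed=config.seed,
    )
    imp_rows = []
    if with_importance:
        subsets = default_feature_subsets(cohort.features.columns)
        combined = subsets.get("combined", list(cohort.features.columns))
        for target in ("G1", "G2", "G3"):
            train, test = balanced_split(cohort, target, spec, seed=config.seed)
            res = train_eval_rf(
                CohortTable(train.features[combined], train.groups),
                CohortTable(test.features[combined], test.groups),
                target,
                n_trees=config.n_trees,
                seed=config.seed + 1,
                with_importance=True,
            )
            for feat, score in res.importance.items():
                imp_rows.append((target, feat, score))
    importance = pd.DataFrame(
        imp_rows, columns=["target", "feature", "importance"]
    )
    return auc, importance
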