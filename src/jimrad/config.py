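"""Run configuration: the analysis settings, with defaults matching the
study protocol (5 quantization levels, 4 distances x 4 angles, 21x21x10
ROI, alpha 0.05, 500 trees, balanced 20/20 train + 10/10 test splits)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    levels: tuple[int, ...] = (8, 16, 32, 64, 128)
    distances: tuple[int, ...] = (1, 2, 3, 4)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    roi_window: tuple[int, int, int] = (21, 21, 10)
    alpha: float = 0.05
    n_trees: int = 500
    n_train_pos: int = 20
    n_train_neg: int = 20
    n_test_pos: int = 10
    n_test_neg: int = 10
    n_reps: int = 25
    histogram_bins: int = 64
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    resample: bool = False  # synthetic volumes are already on a 1 mm grid
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("levels", "distances", "angles", "roi_window",
                     "target_spacing"):
            object.__setattr__(self, name, tuple(getattr(self, name)))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Short stable hash identifying the configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
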