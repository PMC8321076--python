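"""Pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classify import ALL_MODELS


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end pipeline, with field-standard defaults.

    ``manifest`` points at an existing labeled image list; when it is None
    the synthetic generator provides the images.
    """

    out_dir: str = "dermtex_run"
    manifest: str | None = None
    # synthetic generation (used when manifest is None)
    n_images_per_class: int = 200
    image_size: int = 96
    # patch sampling and features
    patch_size: int = 6
    n_per_image: int = 10
    levels: int = 8
    distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    # modeling
    train_fraction: float = 0.75
    models: tuple[str, ...] = ALL_MODELS
    top_k: int = 5
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys in {Path(path).name}: "
                             f"{sorted(unknown)}")
        for key in ("distances", "angles", "models"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)
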