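"""Pipeline configuration: one YAML file driving the whole experiment."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .experiment import ExperimentConfig
from .fusion import FusionConfig
from .synthetic import SyntheticConfig


@dataclass
class PipelineConfig:
    """Bundled settings for the end-to-end leave-one-out evaluation."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    atlas_dir: str | None = None
    out_dir: str = "results"

    def __post_init__(self) -> None:
        ks = self.experiment.k_values
        if any(not 1 <= k <= self.synthetic.n_atlases - 1 for k in ks):
            raise ValueError(
                f"k_values {ks} must lie in [1, n_atlases-1] "
                f"= [1, {self.synthetic.n_atlases - 1}]"
            )


def _coerce(section: dict, cls):
    known = {f for f in cls.__dataclass_fields__}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(section)
    # YAML lists -> tuples where the dataclass expects them
    for key, value in kwargs.items():
        if isinstance(value, list):
            kwargs[key] = tuple(value)
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from YAML; omitted sections take defaults."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return PipelineConfig(
        synthetic=_coerce(payload.get("synthetic", {}), SyntheticConfig),
        fusion=_coerce(payload.get("fusion", {}), FusionConfig),
        experiment=_coerce(payload.get("experiment", {}), ExperimentConfig),
        atlas_dir=payload.get("atlas_dir"),
        out_dir=payload.get("out_dir", "results"),
    )


def _listify(obj):
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


def save_config(config: PipelineConfig, path: str | Path) -> None:
    payload = {
        "synthetic": _listify(asdict(config.synthetic)),
        "fusion": _listify(asdict(config.fusion)),
        "experiment": _listify(asdict(config.experiment)),
        "atlas_dir": config.atlas_dir,
        "out_dir": config.out_dir,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
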