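"""Pipeline configuration: a single YAML mapping with strict key checking."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .network import DEFAULT_KNN, DEFAULT_R_MIN
from .segmentation import DEFAULT_HU_WINDOW


@dataclass
class CohortConfig:
    """Overrides for the synthetic cohort (see ``synthetic.CohortSpec``)."""

    n_animals: int = 5
    shared_driver_strength: float = 0.8
    noise_scale: float = 2.0
    dose_mean_MBq: float = 15.08
    dose_sd_MBq: float = 5.87
    weight_mean_g: float = 27.0
    weight_sd_g: float = 2.0


@dataclass
class NetworkConfig:
    r_min: float = DEFAULT_R_MIN
    knn: int = DEFAULT_KNN
    mode: str = "mouse_average"
    rule: str = "union"


@dataclass
class QuantifyConfig:
    window_min: tuple[float, float] = (45.0, 60.0)
    decay_correct: bool = True


@dataclass
class SegmentationConfig:
    hu_lower: float = DEFAULT_HU_WINDOW[0]
    hu_upper: float = DEFAULT_HU_WINDOW[1]


@dataclass
class InputPaths:
    """Optional real inputs; when ``tac_csv`` is unset the cohort is simulated.

    Volumetric inputs (ct_nii + pet_nii + labels_nii + bone_labels) route
    through the segmentation stage instead of reading TAC CSVs directly.
    """

    tac_csv: str | None = None
    schedule_csv: str | None = None
    metadata_csv: str | None = None
    hu_csv: str | None = None
    ct_nii: str | None = None
    pet_nii: str | None = None
    labels_nii: str | None = None
    bone_labels: dict[str, int] = field(default_factory=dict)


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "outputs"
    log_level: str = "INFO"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    inputs: InputPaths = field(default_factory=InputPaths)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "cohort": CohortConfig,
    "network": NetworkConfig,
    "quantify": QuantifyConfig,
    "segmentation": SegmentationConfig,
    "inputs": InputPaths,
}
_SCALARS = ("seed", "output_dir", "log_level")


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a config from a nested mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS) - set(_SCALARS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig()
    for key in _SCALARS:
        if key in data:
            setattr(cfg, key, data[key])
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data[name] or {}
            if not isinstance(section, dict):
                raise ValueError(f"config section {name!r} must be a mapping")
            valid = {f for f in cls.__dataclass_fields__}
            bad = set(section) - valid
            if bad:
                raise ValueError(f"unknown keys in config section {name!r}: {sorted(bad)}")
            if "window_min" in section:
                section["window_min"] = tuple(section["window_min"])
            setattr(cfg, name, cls(**section))
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)
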