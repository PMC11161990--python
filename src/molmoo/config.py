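"""Run configuration: a YAML-serializable bundle of every stage's settings.

``load(save(config)) == config`` holds exactly, and each run directory gets
a snapshot of the configuration that produced it, so any run is
reproducible from its own outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .autoencoder import LossWeights, ModelConfig, TrainConfig
from .optimizers import AlgorithmParams
from .triage import FilterSpec

__all__ = ["RunConfig", "load_config", "save_config"]

#: The study's five random seeds.
DEFAULT_SEEDS = (42, 182, 625, 511, 310)

DEFAULT_OBJECTIVES = (
    {"name": "binding_affinity", "direction": "minimize",
     "evaluator": "surrogate_admet:binding_affinity"},
    {"name": "sas", "direction": "minimize", "evaluator": "sas"},
    {"name": "bioavailability", "direction": "maximize",
     "evaluator": "surrogate_admet:bioavailability"},
    {"name": "solubility", "direction": "maximize",
     "evaluator": "surrogate_admet:solubility"},
    {"name": "ld50", "direction": "minimize",
     "evaluator": "surrogate_admet:ld50"},
    {"name": "clintox", "direction": "minimize",
     "evaluator": "surrogate_admet:clintox"},
)


@dataclass
class RunConfig:
    dataset_path: str | None = None
    smiles_column: str = "smiles"
    output_dir: str = "runs"
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossWeights = field(default_factory=LossWeights)
    training: TrainConfig = field(default_factory=TrainConfig)
    search: AlgorithmParams = field(default_factory=AlgorithmParams)
    objectives: list[dict] = field(
        default_factory=lambda: [dict(o) for o in DEFAULT_OBJECTIVES])
    filters: FilterSpec = field(default_factory=FilterSpec)
    algorithms: list[str] = field(default_factory=lambda:
                                  ["grea", "hype", "knea", "moeadd",
                                   "ansga3", "nmpso"])
    seeds: list[int] = field(default_factory=lambda: list(DEFAULT_SEEDS))
    # preprocessing
    max_token_length: int = 198
    min_augmentations: int = 2
    augmentation_attempts: int = 10
    split_fractions: tuple[float, float, float] = (0.70, 0.10, 0.20)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["split_fractions"] = list(self.split_fractions)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        converters = {"model": ModelConfig, "loss": LossWeights,
                      "training": TrainConfig, "search": AlgorithmParams,
                      "filters": FilterSpec}
        for key, maker in converters.items():
            if key in data and isinstance(data[key], dict):
                section = dict(data[key])
                for f in fields(maker):
                    if f.name in section and isinstance(section[f.name], list):
                        section[f.name] = tuple(section[f.name])
                data[key] = maker(**section)
        if "split_fractions" in data:
            data["split_fractions"] = tuple(data["split_fractions"])
        return cls(**data)


def save_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))
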