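"""YAML experiment configuration: schema, validation, round-tripping.

One config file describes a whole experiment: the synthetic dataset block,
the fixture-model block, one run block (single run) or a list of run blocks
plus a repeat count (grid sweep). Validation happens before any side
effect and names the offending keys.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import SegModelSpec
from .synth import SplitSpec, SynthPreset, preset
from .train import TrainingConfig

__all__ = ["DatasetConfig", "ExperimentPlan", "load_config", "load_plan",
           "dump_plan", "ConfigError"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass(frozen=True)
class DatasetConfig:
    preset: str = "cup_like"
    n: int = 120
    seed: int = 0
    image_size: int = 64
    split: SplitSpec = field(default_factory=SplitSpec)
    dir: str | None = None
    overrides: dict = field(default_factory=dict)

    def make_preset(self) -> SynthPreset:
        return preset(self.preset, image_size=self.image_size, **self.overrides)


@dataclass
class ExperimentPlan:
    dataset: DatasetConfig
    model: SegModelSpec
    runs: list  # list of (label, TrainingConfig-kwargs dict)
    repeats: int = 1
    base_seed: int = 0

    def __post_init__(self):
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")
        for label, kwargs in self.runs:
            self.training_config(kwargs, run_seed=self.base_seed)  # validates

    @staticmethod
    def training_config(kwargs: dict, run_seed: int) -> TrainingConfig:
        try:
            return TrainingConfig(run_seed=run_seed, **kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid run configuration {kwargs}: {exc}") from exc


def _check_keys(block: dict, allowed: set, name: str, required: set = frozenset()):
    if not isinstance(block, dict):
        raise ConfigError(f"'{name}' must be a mapping")
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in '{name}': {sorted(unknown)}")
    missing = required - set(block)
    if missing:
        raise ConfigError(f"missing keys in '{name}': {sorted(missing)}")


_SPLIT_KEYS = {"train", "test", "calibration", "validation", "seed"}
_DATASET_KEYS = {"preset", "n", "seed", "image_size", "split", "dir",
                 "fg_fraction_range", "boundary_sigma", "noise_sd",
                 "label_flip_band"}
_MODEL_KEYS = {"in_channels", "base_width", "depth", "m_heads", "seed",
               "head_init", "head_bias"}
_RUN_KEYS = {"label", "method", "gamma", "n_warmup", "alpha", "learning_rate",
             "weight_decay", "patience", "max_epochs", "batch_size", "run_seed"}


def _parse_split(block) -> SplitSpec:
    if block is None:
        raise ConfigError("missing keys in 'dataset': ['split']")
    _check_keys(block, _SPLIT_KEYS, "dataset.split",
                required={"train", "test", "calibration", "validation"})
    try:
        return SplitSpec(
            (block["train"], block["test"], block["calibration"], block["validation"]),
            seed=int(block.get("seed", 0)),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid 'dataset.split': {exc}") from exc


def _parse_dataset(block) -> DatasetConfig:
    _check_keys(block, _DATASET_KEYS, "dataset", required={"preset", "n", "split"})
    overrides = {k: block[k] for k in
                 ("fg_fraction_range", "boundary_sigma", "noise_sd", "label_flip_band")
                 if k in block}
    if "fg_fraction_range" in overrides:
        overrides["fg_fraction_range"] = tuple(overrides["fg_fraction_range"])
    cfg = DatasetConfig(
        preset=block["preset"], n=int(block["n"]), seed=int(block.get("seed", 0)),
        image_size=int(block.get("image_size", 64)),
        split=_parse_split(block.get("split")), dir=block.get("dir"),
        overrides=overrides,
    )
    try:
        cfg.make_preset()
    except ValueError as exc:
        raise ConfigError(f"invalid 'dataset': {exc}") from exc
    return cfg


def _parse_model(block) -> SegModelSpec:
    block = block or {}
    _check_keys(block, _MODEL_KEYS, "model")
    try:
        return SegModelSpec(**block)
    except ValueError as exc:
        raise ConfigError(f"invalid 'model': {exc}") from exc


def _parse_run(block, index: int | None = None):
    name = "run" if index is None else f"runs[{index}]"
    _check_keys(block, _RUN_KEYS, name, required={"method"})
    kwargs = {k: v for k, v in block.items() if k not in ("label", "run_seed")}
    label = block.get("label", block["method"])
    try:
        TrainingConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}': {exc}") from exc
    return label, kwargs


def _load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} is not a mapping")
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}")
    return data


def load_config(path):
    """Load a single-run config: dataset + model + run blocks."""
    data = _load_yaml(path)
    _check_keys(data, {"schema_version", "dataset", "model", "run"}, "config",
                required={"dataset", "run"})
    dataset = _parse_dataset(data["dataset"])
    model = _parse_model(data.get("model"))
    label, run_kwargs = _parse_run(data["run"])
    run_seed = int(data["run"].get("run_seed", 0))
    return dataset, model, label, run_kwargs, run_seed


def load_plan(path) -> ExperimentPlan:
    """Load a sweep plan: dataset + model + runs list + repeats + base_seed."""
    data = _load_yaml(path)
    _check_keys(data, {"schema_version", "dataset", "model", "runs", "repeats",
                       "base_seed"}, "plan", required={"dataset", "runs"})
    if not isinstance(data["runs"], list) or not data["runs"]:
        raise ConfigError("'runs' must be a nonempty list")
    runs = [_parse_run(r, i) for i, r in enumerate(data["runs"])]
    labels = [label for label, _ in runs]
    if len(set(labels)) != len(labels):
        raise ConfigError(f"duplicate run labels: {labels}")
    return ExperimentPlan(
        dataset=_parse_dataset(data["dataset"]),
        model=_parse_model(data.get("model")),
        runs=runs,
        repeats=int(data.get("repeats", 1)),
        base_seed=int(data.get("base_seed", 0)),
    )


def dump_plan(plan: ExperimentPlan) -> str:
    """Serialise a plan back to YAML (round-trips through load_plan)."""
    split = plan.dataset.split
    data = {
        "schema_version": SCHEMA_VERSION,
        "dataset": {
            "preset": plan.dataset.preset,
            "n": plan.dataset.n,
            "seed": plan.dataset.seed,
            "image_size": plan.dataset.image_size,
            "split": dict(zip(("train", "test", "calibration", "validation"),
                              [float(f) for f in split.fractions]))
                     | {"seed": split.seed},
            **plan.dataset.overrides,
        },
        "model": asdict(plan.model),
        "runs": [{"label": label, **kwargs} for label, kwargs in plan.runs],
        "repeats": plan.repeats,
        "base_seed": plan.base_seed,
    }
    if plan.dataset.dir:
        data["dataset"]["dir"] = plan.dataset.dir
    return yaml.safe_dump(data, sort_keys=False)
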