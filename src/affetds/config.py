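"""Run configuration: documented defaults, YAML loading, strict validation.

The configuration is a nested mapping with sections ``corpus``,
``preprocess``, ``attack``, ``train``, ``ensemble`` plus the top-level keys
``seed`` and ``out_dir``. Files may use either nesting or flat dotted keys
(``attack.eps: 0.01``). Unknown keys and invalid values are all reported at
once in a single :class:`~affetds._exceptions.ConfigError`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from ._exceptions import ConfigError
from .synthetic import DEFAULT_N_REAL, DEFAULT_N_TOTAL


@dataclass
class CorpusSection:
    n_total: int = DEFAULT_N_TOTAL
    real_fraction: float = DEFAULT_N_REAL / DEFAULT_N_TOTAL
    insert_fraction: float = 0.5
    image_size: int = 224
    texture_amplitude: float = 0.06


@dataclass
class PreprocessSection:
    size: int = 224
    sigma: float = 1.5
    interp: str = "bilinear"


@dataclass
class AttackSection:
    eps: float = 0.03
    alpha: float = 0.007
    iterations: int = 10
    fraction: float = 0.5  # share of each class given adversarial copies
    methods: tuple[str, ...] = ("fgsm", "pgd")


@dataclass
class TrainSection:
    learning_rate: float = 1e-3
    batch_size: int = 16
    patience: int = 5
    max_epochs: int = 50
    finetune_epochs: int = 10  # adversarial fine-tuning epoch cap after clean training
    conv_widths: tuple[int, ...] = (16, 32, 64)
    fc_width: int = 128
    head_pool: str = "flatten"
    head_downsample: int = 2
    weight_decay: float = 1e-4
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple = (1e-4, 1e-3, 1e-2, 1e-1, "reciprocal_dim")


@dataclass
class EnsembleSection:
    threshold: float = 0.5


@dataclass
class RunConfig:
    corpus: CorpusSection = field(default_factory=CorpusSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    attack: AttackSection = field(default_factory=AttackSection)
    train: TrainSection = field(default_factory=TrainSection)
    ensemble: EnsembleSection = field(default_factory=EnsembleSection)
    seed: int = 0
    out_dir: str = "runs"

    def to_dict(self) -> dict:
        out = asdict(self)
        for section in ("attack", "train"):
            for key, value in out[section].items():
                if isinstance(value, tuple):
                    out[section][key] = list(value)
        return out


_SECTIONS = {
    "corpus": CorpusSection,
    "preprocess": PreprocessSection,
    "attack": AttackSection,
    "train": TrainSection,
    "ensemble": EnsembleSection,
}
_TOP_LEVEL = {"seed": int, "out_dir": str}

# (section, key) -> predicate, description. Every rule failure names its key.
_RULES = {
    ("corpus", "n_total"): (lambda v: v >= 2, "must be >= 2"),
    ("corpus", "real_fraction"): (lambda v: 0 < v < 1, "must be in (0, 1)"),
    ("corpus", "insert_fraction"): (lambda v: 0 <= v <= 1, "must be in [0, 1]"),
    ("corpus", "image_size"): (lambda v: v >= 64 and v % 8 == 0, "must be >= 64 and divisible by 8"),
    ("corpus", "texture_amplitude"): (lambda v: v >= 0, "must be >= 0"),
    ("preprocess", "size"): (lambda v: v >= 1, "must be positive"),
    ("preprocess", "sigma"): (lambda v: v >= 0, "must be >= 0"),
    ("preprocess", "interp"): (lambda v: v in ("nearest", "bilinear", "bicubic"), "unknown interpolation"),
    ("attack", "eps"): (lambda v: v >= 0, "must be >= 0"),
    ("attack", "alpha"): (lambda v: v >= 0, "must be >= 0"),
    ("attack", "iterations"): (lambda v: v >= 0, "must be >= 0"),
    ("attack", "fraction"): (lambda v: 0 <= v <= 1, "must be in [0, 1]"),
    ("attack", "methods"): (
        lambda v: all(m in ("fgsm", "pgd") for m in v),
        "entries must be 'fgsm' or 'pgd'",
    ),
    ("train", "learning_rate"): (lambda v: v > 0, "must be positive"),
    ("train", "batch_size"): (lambda v: v >= 1, "must be >= 1"),
    ("train", "patience"): (lambda v: v >= 1, "must be >= 1"),
    ("train", "max_epochs"): (lambda v: v >= 1, "must be >= 1"),
    ("train", "finetune_epochs"): (lambda v: v >= 0, "must be >= 0"),
    ("train", "head_pool"): (lambda v: v in ("max", "avg", "flatten"), "must be 'max', 'avg' or 'flatten'"),
    ("train", "head_downsample"): (lambda v: v >= 1, "must be >= 1"),
    ("train", "weight_decay"): (lambda v: v >= 0, "must be >= 0"),
    ("ensemble", "threshold"): (lambda v: 0 <= v <= 1, "must be in [0, 1]"),
}


def _coerce(section: str, key: str, value: Any, target_type, errors: list[str]) -> Any:
    dotted = f"{section}.{key}" if section else key
    try:
        if target_type in (tuple, "tuple"):
            return tuple(value)
        if target_type is int:
            if isinstance(value, bool) or (isinstance(value, float) and value != int(value)):
                raise TypeError
            return int(value)
        if target_type is float:
            if isinstance(value, bool):
                raise TypeError
            return float(value)
        if target_type is str:
            if not isinstance(value, str):
                raise TypeError
            return value
    except (TypeError, ValueError):
        errors.append(f"{dotted}: expected {getattr(target_type, '__name__', target_type)}, got {value!r}")
        return None
    return value


def _nested(raw: dict, errors: list[str]) -> dict:
    """Flatten-aware view: dotted keys become nested entries."""
    out: dict[str, Any] = {}
    for key, value in raw.items():
        if "." in key:
            section, sub = key.split(".", 1)
            out.setdefault(section, {})
            if not isinstance(out[section], dict):
                errors.append(f"{section}: mixed scalar and section use")
                continue
            out[section][sub] = value
        elif isinstance(value, dict):
            out.setdefault(key, {})
            out[key].update(value)
        else:
            out[key] = value
    return out


def validate_config(raw: dict) -> RunConfig:
    """Merge a raw mapping over defaults, reporting every problem at once."""
    errors: list[str] = []
    raw = _nested(raw or {}, errors)
    config = RunConfig()

    for key, value in raw.items():
        if key in _TOP_LEVEL:
            coerced = _coerce("", key, value, _TOP_LEVEL[key], errors)
            if coerced is not None:
                setattr(config, key, coerced)
        elif key in _SECTIONS:
            section_obj = getattr(config, key)
            known = {f.name: f for f in fields(_SECTIONS[key])}
            if not isinstance(value, dict):
                errors.append(f"{key}: expected a mapping of settings")
                continue
            for sub, sub_value in value.items():
                if sub not in known:
                    errors.append(f"{key}.{sub}: unknown key")
                    continue
                default = getattr(section_obj, sub)
                target = tuple if isinstance(default, tuple) else type(default)
                coerced = _coerce(key, sub, sub_value, target, errors)
                if coerced is not None:
                    setattr(section_obj, sub, coerced)
        else:
            errors.append(f"{key}: unknown key")

    for (section, key), (predicate, message) in _RULES.items():
        value = getattr(getattr(config, section), key)
        try:
            ok = predicate(value)
        except TypeError:
            ok = False
        if not ok:
            errors.append(f"{section}.{key}: {message} (got {value!r})")

    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(sorted(errors)))
    return config


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config file; an empty or missing-path file gives defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return validate_config(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config as YAML; load_config(save_config(c)) round-trips."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
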