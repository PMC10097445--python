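"""Run configuration: YAML file with strict keys and seed fan-out.

One global seed deterministically derives per-stage sub-seeds (simulate,
train, exp2, mediate, ...) so any stage can be re-run independently and
reproduce its part of a pipeline run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["RunConfig", "load_config", "stage_seed"]

_STAGES = ("simulate", "preprocess", "train", "loso", "label", "exp2", "stats")

_KNOWN_KEYS: dict[str, set[str]] = {
    "": {"seed", "log_level", "simulator", "preprocess", "model", "stats", "io"},
    "simulator": {
        "rate", "noise_sd", "gravity", "subject_jitter", "amp_cv", "freq_cv",
        "duration_per_activity", "n_subjects", "classes",
    },
    "preprocess": {"width", "overlap", "target_rate"},
    "model": {
        "input_channels", "hidden1", "hidden2", "dropout_p", "n_classes",
        "minibatch", "max_epochs", "learning_rate", "momentum",
    },
    "stats": {"n_boot", "ci_level", "exp2_n_subjects", "missing_stress_prob"},
    "io": {"out_dir"},
}

_CLASS_KEYS = {"freq", "amp", "noise_sd", "gravity", "pulse_height", "pulse_width"}


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    simulator: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    io: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "log_level": self.log_level,
            "simulator": self.simulator, "preprocess": self.preprocess,
            "model": self.model, "stats": self.stats, "io": self.io,
        }


def _check_keys(section: str, mapping: dict) -> None:
    unknown = set(mapping) - _KNOWN_KEYS[section]
    if unknown:
        where = f"section {section!r}" if section else "top level"
        raise ValueError(f"unknown config keys at {where}: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Load a YAML run config, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    _check_keys("", raw)
    for section in ("simulator", "preprocess", "model", "stats", "io"):
        sub = raw.get(section) or {}
        if not isinstance(sub, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        _check_keys(section, sub)
    classes = (raw.get("simulator") or {}).get("classes") or {}
    for label, params in classes.items():
        unknown = set(params) - _CLASS_KEYS
        if unknown:
            raise ValueError(f"unknown motion-model keys for class {label!r}: {sorted(unknown)}")
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        simulator=raw.get("simulator") or {},
        preprocess=raw.get("preprocess") or {},
        model=raw.get("model") or {},
        stats=raw.get("stats") or {},
        io=raw.get("io") or {},
    )


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic sub-seed for a pipeline stage (< 2**31)."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0] >> np.uint32(1))
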