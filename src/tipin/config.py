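"""Threshold and run configuration shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml

__all__ = ["Thresholds", "RunConfig", "load_config"]


@dataclass(frozen=True)
class Thresholds:
    """Admission thresholds for the identification sweep.

    ``r`` is the reliability threshold on the 1-999 score scale; ``sigma``,
    ``omega`` and ``theta`` gate the CC/MF/BP minimal similarities; ``gamma``
    gates the joint coexpression quantity (no published value; 0.01 is this
    package's default -- scan it for your data); ``phi`` is the active
    threshold on normalized expression.
    """

    r: int = 999
    sigma: float = 0.7
    omega: float = 0.6
    theta: float = 0.1
    gamma: float = 0.01
    phi: float = 0.1

    def __post_init__(self) -> None:
        if not 1 <= self.r <= 999:
            raise ValueError(f"r must be in [1, 999], got {self.r}")
        for name in ("sigma", "omega", "theta", "gamma", "phi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class RunConfig:
    """Behavioural switches that are not admission thresholds."""

    min_size: int = 2
    jq_denominator: str = "window"  # "window" (mean over window) or "T"
    strict_localization: bool = False  # unannotated proteins: all-zeros vs all-ones
    dedup: str = "exact"  # catalog dedup: "exact" or "none"
    exclude_evidence: tuple[str, ...] = ()
    n_cycles: int = 1  # cycle-averaging of raw expression columns

    def __post_init__(self) -> None:
        if self.jq_denominator not in ("window", "T"):
            raise ValueError(f"jq_denominator must be 'window' or 'T'")
        if self.dedup not in ("exact", "none"):
            raise ValueError("dedup must be 'exact' or 'none'")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


def load_config(path: str | Path) -> tuple[Thresholds, RunConfig]:
    """Load a YAML config file; unknown keys are an error."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    t_fields = Thresholds.__dataclass_fields__.keys()
    c_fields = RunConfig.__dataclass_fields__.keys()
    t_kwargs, c_kwargs = {}, {}
    for key, value in data.items():
        if key in t_fields:
            t_kwargs[key] = value
        elif key in c_fields:
            if key == "exclude_evidence":
                value = tuple(value)
            c_kwargs[key] = value
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")
    return Thresholds(**t_kwargs), RunConfig(**c_kwargs)


def dump_config(thresholds: Thresholds, config: RunConfig, path: str | Path) -> None:
    data = {**asdict(thresholds), **asdict(config)}
    data["exclude_evidence"] = list(data["exclude_evidence"])
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
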