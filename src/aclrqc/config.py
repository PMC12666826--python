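"""TOML configuration: detection thresholds, classifier thresholds and the
trace column map, bundled for the command-line tools."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .metrics import DetectionParams
from .outcome import ClassifierThresholds
from .trace_io import ColumnMap

__all__ = ["AnalysisConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    detection: DetectionParams = DetectionParams()
    thresholds: ClassifierThresholds = ClassifierThresholds()
    column_map: ColumnMap = ColumnMap()


def _section(obj) -> dict:
    return dataclasses.asdict(obj)


def load_config(path: Union[str, Path]) -> AnalysisConfig:
    """Load an AnalysisConfig; absent sections/keys keep their defaults."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)

    def build(cls, section):
        if section not in data:
            return cls()
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data[section]) - fields
        if unknown:
            raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
        return cls(**data[section])

    return AnalysisConfig(
        detection=build(DetectionParams, "detection"),
        thresholds=build(ClassifierThresholds, "thresholds"),
        column_map=build(ColumnMap, "column_map"),
    )


def save_config(config: AnalysisConfig, path: Union[str, Path]) -> Path:
    path = Path(path)
    lines = []
    for section, obj in (
        ("detection", config.detection),
        ("thresholds", config.thresholds),
        ("column_map", config.column_map),
    ):
        lines.append(f"[{section}]")
        for key, val in _section(obj).items():
            if val is None:
                continue
            if isinstance(val, bool):
                rep = "true" if val else "false"
            elif isinstance(val, (int, float)):
                rep = repr(val)
            else:
                rep = f'"{val}"'
            lines.append(f"{key} = {rep}")
        lines.append("")
    path.write_text("\n".join(lines))
    return path
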