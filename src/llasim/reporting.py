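"""Run manifests and CSV/JSON writers for the command-line tools.

Every CLI run emits a ``manifest.json`` capturing the fully resolved
parameter set (including the infectiousness-boundary switch), the package
version, a timestamp and any seeds, so that a run can be reproduced exactly
from its manifest.  Numeric output is written at 12 significant digits.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .interventions import Intervention
from .parameters import BiologyParams, PopulationParams

__all__ = ["RunManifest", "write_csv", "write_json", "get_logger"]

_FLOAT_FORMAT = "%.12g"

logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")


def get_logger(name: str = "llasim") -> logging.Logger:
    logger = logging.getLogger(name)
    logger.setLevel(logging.INFO)
    return logger


def _round12(obj: Any) -> Any:
    if isinstance(obj, float):
        return float(_FLOAT_FORMAT % obj)
    if isinstance(obj, dict):
        return {k: _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round12(v) for v in obj]
    return obj


@dataclass(frozen=True)
class RunManifest:
    """Resolved inputs of one CLI run, sufficient to reproduce it."""

    subcommand: str
    biology: BiologyParams
    population: PopulationParams | None = None
    interventions: tuple[Intervention, ...] = ()
    options: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "subcommand": self.subcommand,
            "version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "biology": dataclasses.asdict(self.biology),
            "population": (
                dataclasses.asdict(self.population) if self.population else None
            ),
            "interventions": [iv.to_dict() for iv in self.interventions],
            "options": dict(self.options),
            "seed": self.seed,
        }

    def write(self, out_dir: Path) -> Path:
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(_round12(self.to_dict()), indent=2) + "\n")
        return path


def write_csv(frame: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT, lineterminator="\r\n")
    return path


def write_json(payload: dict[str, Any], path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_round12(payload), indent=2) + "\n")
    return path
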