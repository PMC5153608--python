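"""Toolkit-wide configuration with the published defaults.

Every default mirrors the value found optimal or stated in the underlying
study: descriptor k=16, S=1, icosahedron, half-orientation; SVM decade
grids C = 10^-2..10^3 and gamma = 10^-5..10^2; tracer thresholds 1.12
(florbetapir), 1.36 (florbetaben), 1.15 (PiB on the sPAP scale).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .classify import DEFAULT_C_GRID, DEFAULT_GAMMA_GRID
from .hog3d import HOGParams
from .suvr import TRACER_THRESHOLDS

__all__ = ["ToolConfig"]


@dataclass
class ToolConfig:
    """Bundled defaults for the CLI and batch pipelines."""

    hog: HOGParams = field(default_factory=HOGParams)
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    n_folds: int = 10
    suvr_thresholds: dict = field(default_factory=lambda: dict(TRACER_THRESHOLDS))
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ToolConfig":
        d = json.loads(text)
        hog = HOGParams(**d.pop("hog")) if "hog" in d else HOGParams()
        cfg = cls(hog=hog)
        for key in ("n_folds", "seed"):
            if key in d:
                setattr(cfg, key, int(d[key]))
        if "c_grid" in d:
            cfg.c_grid = tuple(float(x) for x in d["c_grid"])
        if "gamma_grid" in d:
            cfg.gamma_grid = tuple(float(x) for x in d["gamma_grid"])
        if "suvr_thresholds" in d:
            cfg.suvr_thresholds = {k: float(v) for k, v in d["suvr_thresholds"].items()}
        return cfg

    @classmethod
    def from_file(cls, path: str) -> "ToolConfig":
        with open(path) as fh:
            return cls.from_json(fh.read())
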