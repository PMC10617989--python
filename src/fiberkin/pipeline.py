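"""Run configuration, provenance and stage ordering.

A run is a sequence of named stages over one movie.  Stages must be
requested in a dependency-consistent order (tracking before displacement
or PCA, end detection before sqrt-time fits, fits before mechanics);
each stage writes CSV/JSON artifacts plus a provenance record carrying
the configuration, its hash, the seed and the package version, so a
rerun with identical configuration reproduces every stochastic stage
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__

__all__ = ["RunConfig", "stage_order_valid", "provenance_record",
           "subseed", "STAGE_DEPS"]

# stage -> stages that must have run before it
STAGE_DEPS = {
    "simulate": [],
    "track": [],
    "displace": ["track"],
    "pca": [],
    "ends": [],
    "fit": ["ends"],
    "mechanics": ["fit"],
    "cilia": [],
    "calcium": [],
}


@dataclass
class RunConfig:
    """Calibration and analysis parameters of a run.

    Written/read as a simple ``key = value`` text format; command-line
    flags override file values.  Physical-unit outputs require
    ``pixel_size`` and ``frame_interval``.
    """

    pixel_size: float | None = None      # um/px
    frame_interval: float | None = None  # s
    exposure: float = 0.025              # s
    sigma_x: float = 3.5
    sigma_y: float = 1.9
    smooth_sigma: float = 5.8
    n_iter: int = 100
    width_limit: float = 10.0
    bin_um: float = 2.0
    r_f: float = 100e-9                  # m
    eta: float = 1.0e-3                  # Pa s
    L: float = 3.0e-3                    # m
    prefactor: float = 2.0 / np.sqrt(np.pi)
    seed: int = 0
    out_dir: str = "."
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cfg = cls()
        known = {f for f in cfg.__dataclass_fields__ if f != "extra"}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key in known:
                current = getattr(cfg, key)
                if key in ("n_iter", "seed"):
                    setattr(cfg, key, int(val))
                elif key == "out_dir":
                    cfg.out_dir = val
                else:
                    setattr(cfg, key, float(val))
            else:
                cfg.extra[key] = val
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration (for provenance)."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_order_valid(stages: list[str]) -> None:
    """Raise with the missing upstream stage if the order is invalid."""
    seen: set[str] = set()
    for stage in stages:
        if stage not in STAGE_DEPS:
            raise ValueError(f"unknown stage {stage!r}")
        for dep in STAGE_DEPS[stage]:
            if dep not in seen:
                raise ValueError(
                    f"stage {stage!r} requires {dep!r} to run first")
        seen.add(stage)


def subseed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed derived from the top-level seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def provenance_record(config: RunConfig, stage: str, inputs: dict) -> dict:
    """Machine-readable provenance attached to every output artifact."""
    return {
        "stage": stage,
        "package": "fiberkin",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "stage_seed": subseed(config.seed, stage),
        "inputs": inputs,
    }
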