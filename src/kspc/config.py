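"""Run configuration shared by the CLI commands.

A RunConfig collects the tunables of a segmentation run and can be loaded
from a plain ``key = value`` text file (lists comma-separated, '#' comments).
Values are validated against the same preconditions the library operations
enforce.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .contours import DEFAULT_LEVELS
from .grid import Bandwidth


@dataclass
class RunConfig:
    bandwidth: Bandwidth | None = None
    levels: tuple = DEFAULT_LEVELS
    margin_voxels: int = 8
    robust_fraction: float = 0.10
    truncation_radius: float = 6.0
    prob_cutoff: float = 0.5
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.bandwidth is not None and not isinstance(self.bandwidth, Bandwidth):
            self.bandwidth = Bandwidth(*self.bandwidth)
        self.levels = tuple(float(v) for v in self.levels)
        if any(not (0.0 < om < 1.0) for om in self.levels):
            raise ValueError("levels must lie strictly inside (0, 1)")
        if self.margin_voxels < 0:
            raise ValueError("margin_voxels must be non-negative")
        if not (0.0 <= self.robust_fraction <= 1.0):
            raise ValueError("robust_fraction must be in [0, 1]")
        if self.truncation_radius <= 0:
            raise ValueError("truncation_radius must be positive")
        if not (0.0 <= self.prob_cutoff <= 1.0):
            raise ValueError("prob_cutoff must be in [0, 1]")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a plain key = value file into a RunConfig."""
        known = {f.name for f in fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
            if key == "bandwidth":
                kwargs[key] = Bandwidth(*(float(v) for v in value.split(",")))
            elif key == "levels":
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif key in ("margin_voxels", "seed"):
                kwargs[key] = int(value)
            elif key in ("robust_fraction", "truncation_radius", "prob_cutoff"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)
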