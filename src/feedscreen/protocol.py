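"""Texture-analyzer compression protocol constants.

The screening test axially compresses a vertically held filament piece in a
texture analyzer and records force versus probe travel during both the
compression stroke and the release stroke.  The defaults reproduce the
published rig protocol: 15 mm of travel at 3.15 mm/s (the roller speed of a
consumer FDM printer's feeding gears), a 0.05 N trigger force below which the
instrument records nothing, and 5 cm specimens of standard 1.75 mm filament
held in conical end caps.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path


@dataclass(frozen=True)
class ProtocolConfig:
    """Constants of the compress-and-release screening protocol.

    Parameters
    ----------
    compression_speed : float
        Probe speed in mm/s.  Matches the printer's roller feed speed.
    compression_distance : float
        Total compression travel in mm.
    trigger_force : float
        Instrument trigger in N; data acquisition starts at this force and a
        specimen that never reaches it is *floppy* (not testable).
    specimen_length : float
        Free length of the filament piece between the end caps, mm.
    specimen_diameter : float
        Filament diameter, mm (standard FDM stock is 1.75 mm).
    grid_points_compression, grid_points_release : int
        Number of uniform distance stations the compression and release
        strokes are resampled onto before normalization and comparison.
    """

    compression_speed: float = 3.15
    compression_distance: float = 15.0
    trigger_force: float = 0.05
    specimen_length: float = 50.0
    specimen_diameter: float = 1.75
    grid_points_compression: int = 128
    grid_points_release: int = 128

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not value > 0:
                raise ValueError(f"{f.name} must be strictly positive, got {value!r}")

    @property
    def grid_points_total(self) -> int:
        return self.grid_points_compression + self.grid_points_release

    @classmethod
    def from_json(cls, path: str | Path) -> "ProtocolConfig":
        """Load a flat key/value JSON config; missing keys take the defaults."""
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")
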