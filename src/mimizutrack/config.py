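"""Run configuration: resolution of flags, config files, and defaults.

Precedence is flags > config file > defaults; each resolved key remembers
where its value came from, and the resolved configuration is serialized
next to every output so a run can be reproduced exactly from its dump.

Config files are flat ``key=value`` text (UTF-8, '#' comments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Union

from .imaging_io import Calibration
from .preprocessing import CircleROI, circle_from_marks

__all__ = ["RunConfig", "parse_config_file", "parse_roi", "parse_point"]

DEFAULTS: dict[str, Any] = {
    "threshold": "auto",
    "polarity": "dark_object",
    "min_fragment_area": 50,
    "min_spur": 5.0,
    "mm_per_pixel": 0.2,
    "frame_interval": 1.0,
    "roi": None,
    "tail_seed": None,
}


def parse_roi(text: str) -> CircleROI:
    """Parse ``"cx,cy,r"`` or three rim marks ``"x1,y1;x2,y2;x3,y3"``."""
    text = text.strip()
    if ";" in text:
        parts = text.split(";")
        if len(parts) != 3:
            raise ValueError(f"expected three rim marks, got {text!r}")
        marks = []
        for p in parts:
            x, y = (float(v) for v in p.split(","))
            marks.append((x, y))
        return circle_from_marks(*marks)
    vals = [float(v) for v in text.split(",")]
    if len(vals) != 3:
        raise ValueError(f"expected cx,cy,r, got {text!r}")
    return CircleROI(center_xy=(vals[0], vals[1]), radius=vals[2])


def parse_point(text: str) -> tuple[float, float]:
    """Parse an ``"x,y"`` pixel coordinate."""
    vals = [float(v) for v in text.split(",")]
    if len(vals) != 2:
        raise ValueError(f"expected x,y, got {text!r}")
    return (vals[0], vals[1])


def parse_config_file(path: str) -> dict[str, str]:
    """Read a flat key=value config file into a raw string dict."""
    out: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key=value")
            key, _, value = line.partition("=")
            value = value.split("#", 1)[0]  # strip inline comments
            out[key.strip()] = value.strip()
    return out


def _coerce(key: str, value):
    """Convert a raw (possibly string) config value to its typed form."""
    if value is None or not isinstance(value, str):
        return value
    if key == "threshold":
        return value if value == "auto" else float(value)
    if key in ("mm_per_pixel", "frame_interval", "min_spur"):
        return float(value)
    if key == "min_fragment_area":
        return int(value)
    if key == "roi":
        return parse_roi(value)
    if key == "tail_seed":
        x, y = parse_point(value)
        return (y, x)  # CSV/CLI convention (x, y) -> internal (row, col)
    return value


@dataclass
class RunConfig:
    """Fully resolved tracking configuration.

    ``tail_seed`` is stored internally as ``(row, col)``; the CLI and config
    files specify it as ``x,y``.
    """

    roi: CircleROI
    threshold: Union[float, str] = "auto"
    polarity: str = "dark_object"
    min_fragment_area: int = 50
    min_spur: float = 5.0
    calibration: Calibration = field(default_factory=Calibration)
    tail_seed: Optional[tuple[float, float]] = None
    provenance: dict[str, str] = field(default_factory=dict)

    @classmethod
    def resolve(cls, flags: Optional[dict] = None,
                file_values: Optional[dict] = None) -> "RunConfig":
        """Build a config from flag values, file values, and defaults.

        ``flags`` holds only explicitly supplied values (string or typed);
        ``file_values`` is the raw dict from :func:`parse_config_file`.
        """
        flags = flags or {}
        file_values = file_values or {}
        resolved: dict[str, Any] = {}
        provenance: dict[str, str] = {}
        for key, default in DEFAULTS.items():
            if key in flags and flags[key] is not None:
                resolved[key] = _coerce(key, flags[key])
                provenance[key] = "flag"
            elif key in file_values:
                resolved[key] = _coerce(key, file_values[key])
                provenance[key] = "file"
            else:
                resolved[key] = default
                provenance[key] = "default"
        if resolved["roi"] is None:
            raise ValueError("no ROI given: supply --roi or a config file")
        return cls(
            roi=resolved["roi"],
            threshold=resolved["threshold"],
            polarity=resolved["polarity"],
            min_fragment_area=resolved["min_fragment_area"],
            min_spur=resolved["min_spur"],
            calibration=Calibration(
                mm_per_pixel=resolved["mm_per_pixel"],
                frame_interval=resolved["frame_interval"],
            ),
            tail_seed=resolved["tail_seed"],
            provenance=provenance,
        )

    def dump(self, path: str) -> None:
        """Serialize as a config file that reproduces this run exactly."""
        cx, cy = self.roi.center_xy
        lines = [
            "# resolved run configuration (key=value; source noted per key)",
            f"mm_per_pixel={self.calibration.mm_per_pixel!r}"
            f"  # {self.provenance.get('mm_per_pixel', 'set')}",
            f"frame_interval={self.calibration.frame_interval!r}"
            f"  # {self.provenance.get('frame_interval', 'set')}",
            f"threshold={self.threshold}  # {self.provenance.get('threshold', 'set')}",
            f"polarity={self.polarity}  # {self.provenance.get('polarity', 'set')}",
            f"min_fragment_area={self.min_fragment_area}"
            f"  # {self.provenance.get('min_fragment_area', 'set')}",
            f"min_spur={self.min_spur!r}  # {self.provenance.get('min_spur', 'set')}",
            f"roi={cx!r},{cy!r},{self.roi.radius!r}"
            f"  # {self.provenance.get('roi', 'set')}",
        ]
        if self.tail_seed is not None:
            row, col = self.tail_seed
            lines.append(
                f"tail_seed={col!r},{row!r}  # {self.provenance.get('tail_seed', 'set')}"
            )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
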