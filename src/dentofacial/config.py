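"""Pipeline configuration shared by the superimposition layer and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import DomainError

DEFAULT_SCALE = 15.56  # mean bizygomatic-width / tooth-width ratio
DEFAULT_EXTRUSION_MM = 6.0
DEFAULT_ALPHA = 0.05


@dataclass
class PipelineConfig:
    """Protocol presets; all overridable, defaults are the study values."""

    scale: float = DEFAULT_SCALE
    extrusion_mm: float = DEFAULT_EXTRUSION_MM
    mode: str = "zygion"  # transverse tangency landmark pair: zygion | alare
    smoothing_iters: int = 5
    cap_depth: float | None = None  # None -> 2 x posterior tooth depth
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    out_dir: str = "."
    scale_after_alignment: bool = False

    def __post_init__(self):
        if not (self.scale > 0):
            raise DomainError(f"scale must be positive, got {self.scale}")
        if not (self.extrusion_mm > 0):
            raise DomainError(f"extrusion must be positive, got {self.extrusion_mm}")
        if not (0 < self.alpha < 1):
            raise DomainError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.mode not in ("zygion", "alare"):
            raise DomainError(f"mode must be 'zygion' or 'alare', got {self.mode!r}")
        if self.smoothing_iters < 0:
            raise DomainError("smoothing_iters must be >= 0")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat key-value text config: `key = value` per line, # comments."""
        kwargs = {}
        numeric = {
            "scale": float,
            "extrusion_mm": float,
            "smoothing_iters": int,
            "cap_depth": float,
            "alpha": float,
            "seed": int,
        }
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise DomainError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key in numeric:
                kwargs[key] = numeric[key](val)
            elif key in ("mode", "out_dir"):
                kwargs[key] = val
            elif key == "scale_after_alignment":
                kwargs[key] = val.lower() in ("1", "true", "yes")
            else:
                raise DomainError(f"{path}:{lineno}: unknown config key {key!r}")
        return cls(**kwargs)
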