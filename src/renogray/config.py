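"""Tool configuration: brightness ranges, rounding policy, significance
level and phantom defaults, loaded from a JSON file and validated at
startup (the CLI refuses to run with a non-tiling range configuration)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .errors import ConfigurationError
from .grayscale import Band, BrightnessRanges, default_ranges
from .normalization import RoundingPolicy
from .phantom import PhantomSpec


@dataclass
class ToolConfig:
    ranges: BrightnessRanges
    rounding_policy: RoundingPolicy = RoundingPolicy("exact_factor")
    alpha: float = 0.05
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    log_level: str = "info"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")


def default_config() -> ToolConfig:
    """Built-in configuration: 14 fallback bands, exact-factor rounding,
    alpha 0.05, default phantom."""
    return ToolConfig(ranges=default_ranges())


def _ranges_from_payload(payload: list[Mapping]) -> BrightnessRanges:
    bands = []
    for entry in payload:
        try:
            bands.append(
                Band(
                    lo=int(entry["lo"]),
                    hi=int(entry["hi"]),
                    tissue_label=str(entry["tissue_label"]),
                    color=tuple(int(c) for c in entry["color"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"bad band entry {entry!r}: {exc}") from exc
    return BrightnessRanges(bands=bands, source="config")


def load_config(path: str | Path) -> ToolConfig:
    """Load and validate a JSON configuration file.

    Schema (all keys optional, defaults apply):
    ``{"ranges": [{"lo", "hi", "tissue_label", "color": [r,g,b]}, ...],
    "rounding_policy": "exact_factor"|"paper_compat", "alpha": 0.05,
    "phantom": {<PhantomSpec fields>}, "log_level": "info"}``
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path} is not valid JSON: {exc}") from exc
    cfg = default_config()
    if "ranges" in payload:
        cfg.ranges = _ranges_from_payload(payload["ranges"])
    if "rounding_policy" in payload:
        cfg.rounding_policy = RoundingPolicy(payload["rounding_policy"])
    if "alpha" in payload:
        cfg.alpha = float(payload["alpha"])
    if "phantom" in payload:
        try:
            cfg.phantom = PhantomSpec(**payload["phantom"])
        except TypeError as exc:
            raise ConfigurationError(f"bad phantom spec: {exc}") from exc
    if "log_level" in payload:
        cfg.log_level = str(payload["log_level"])
    cfg.__post_init__()
    return cfg
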