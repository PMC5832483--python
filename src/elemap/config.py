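"""Run configuration: one structured YAML file shared by all subcommands.

Every section is optional and falls back to documented defaults; unknown
keys are rejected so typos fail loudly.  The parsed configuration is echoed
into each output directory's manifest for reproducibility.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigError
from .gridding import RasterGeometry, ShapeCorrection
from .imageops import DisplaySettings
from .segmentation import ScanTiming
from .tra import TRADialect

_SECTION_KEYS = {
    "dialect": {
        "delimiter",
        "n_header_rows",
        "time_column",
        "time_unit",
        "isotope_columns",
        "decimal_mark",
    },
    "timing": {
        "first_line_start",
        "line_duration",
        "line_interval",
        "n_lines",
        "blank_margin",
    },
    "geometry": {"raster_rate", "line_spacing", "scan_direction", "origin"},
    "correction": {"per_line_offset", "per_file_offset", "shear"},
    "display": {"lo", "hi", "gamma", "colormap", "clip_negative"},
    "background": {"method", "scope", "subtract"},
    "smoothing": {"half_width"},
    "quant": {
        "mode",
        "internal_element",
        "internal_value",
        "standard_table",
        "oxide_mode",
        "isotopes",
    },
    "paths": {"series", "grids", "out"},
}


@dataclass
class RunConfig:
    """Validated, section-structured run configuration."""

    raw: dict[str, Any] = field(default_factory=dict)
    source_text: str = ""

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data, source_text=text)

    @classmethod
    def from_dict(cls, data: dict[str, Any], source_text: str = "") -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping of sections")
        for section, content in data.items():
            if section not in _SECTION_KEYS:
                raise ConfigError(
                    f"unknown config section {section!r}; known: {sorted(_SECTION_KEYS)}"
                )
            if content is None:
                continue
            if not isinstance(content, dict):
                raise ConfigError(f"config section {section!r} must be a mapping")
            unknown = set(content) - _SECTION_KEYS[section]
            if unknown:
                raise ConfigError(
                    f"unknown key(s) {sorted(unknown)} in config section {section!r}"
                )
        return cls(raw=data, source_text=source_text or yaml.safe_dump(data))

    def section(self, name: str) -> dict[str, Any]:
        return dict(self.raw.get(name) or {})

    def dialect(self, **overrides: Any) -> TRADialect:
        kw = {**self.section("dialect"), **_drop_none(overrides)}
        if "isotope_columns" in kw and kw["isotope_columns"] is not None:
            kw["isotope_columns"] = tuple(
                (c, str(lab)) for c, lab in kw["isotope_columns"]
            )
        return TRADialect(**kw)

    def timing(self, **overrides: Any) -> ScanTiming:
        kw = {**self.section("timing"), **_drop_none(overrides)}
        missing = {"first_line_start", "line_duration", "line_interval", "n_lines"} - set(kw)
        if missing:
            raise ConfigError(f"timing section missing required key(s): {sorted(missing)}")
        return ScanTiming(**kw)

    def geometry(self, **overrides: Any) -> RasterGeometry:
        kw = {**self.section("geometry"), **_drop_none(overrides)}
        missing = {"raster_rate", "line_spacing"} - set(kw)
        if missing:
            raise ConfigError(f"geometry section missing required key(s): {sorted(missing)}")
        if "origin" in kw:
            kw["origin"] = tuple(kw["origin"])
        return RasterGeometry(**kw)

    def correction(self, **overrides: Any) -> ShapeCorrection:
        kw = {**self.section("correction"), **_drop_none(overrides)}
        if "per_file_offset" in kw and kw["per_file_offset"] is not None:
            kw["per_file_offset"] = {int(k): float(v) for k, v in kw["per_file_offset"].items()}
        return ShapeCorrection(**kw)

    def display(self, **overrides: Any) -> DisplaySettings:
        kw = {**self.section("display"), **_drop_none(overrides)}
        return DisplaySettings(**kw)

    def sha256(self) -> str:
        return hashlib.sha256(self.source_text.encode()).hexdigest()


def _drop_none(d: dict[str, Any]) -> dict[str, Any]:
    return {k: v for k, v in d.items() if v is not None}


def write_manifest(
    out_dir: str | Path,
    command: str,
    inputs: dict[str, Any],
    config: RunConfig | None = None,
    seed: int | None = None,
) -> Path:
    """Drop a reproducibility record alongside a subcommand's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config_sha256": config.sha256() if config is not None else None,
        "config": config.raw if config is not None else None,
        "package_version": __version__,
        "seed": seed,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
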