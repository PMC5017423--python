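"""Analysis configuration: defaults, flat key/value files, provenance.

Defaults mirror the fabricated device and acquisition this package targets:
16 um diameter x 48 um long PDMS pillars (E = 0.5 MPa) on a 23 um pitch,
imaged at 25 fps.  A config file is a flat list of ``section.key = value``
lines (``#`` comments allowed); JSON with the same dotted keys also works.
Unknown keys are rejected.  The effective configuration (file + overrides)
is serialised next to every run's outputs together with a content hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

from .mechanics import (
    ElasticMaterial,
    PillarGeometry,
    SpringConstant,
    spring_constant,
)

__all__ = ["AnalysisConfig", "load_config"]


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


@dataclass
class AnalysisConfig:
    # pillar geometry and material
    pillar_diameter_um: float = 16.0
    pillar_length_um: float = 48.0
    youngs_modulus_mpa: float = 0.5
    #: explicit stiffness override; when set, the beam formula is bypassed
    spring_constant_n_per_m: float | None = None
    # array geometry and acquisition
    pitch_um: float = 23.0
    pixel_size_um: float = 0.5
    frame_rate_fps: float = 25.0
    # detection
    expected_radius_px: float = 16.0
    min_separation_px: float | None = None  # default: 0.8 * pitch in px
    invert: bool = False
    # tracking
    search_window_px: float = 10.0
    quality_threshold: float = 0.5
    reference_method: str = "percentile"
    # beat segmentation
    min_beat_amplitude_um: float = 0.5
    min_beat_separation_s: float = 0.3
    histogram_bins: int = 36
    #: where the values came from: config file path and CLI overrides
    provenance: dict = field(default_factory=dict)

    # flat dotted keys <-> dataclass fields
    _KEYMAP = {
        "pillar.diameter_um": "pillar_diameter_um",
        "pillar.length_um": "pillar_length_um",
        "pillar.spring_constant_n_per_m": "spring_constant_n_per_m",
        "material.youngs_modulus_mpa": "youngs_modulus_mpa",
        "array.pitch_um": "pitch_um",
        "acquisition.pixel_size_um": "pixel_size_um",
        "acquisition.frame_rate_fps": "frame_rate_fps",
        "detect.expected_radius_px": "expected_radius_px",
        "detect.min_separation_px": "min_separation_px",
        "detect.invert": "invert",
        "track.search_window_px": "search_window_px",
        "track.quality_threshold": "quality_threshold",
        "track.reference_method": "reference_method",
        "beat.min_amplitude_um": "min_beat_amplitude_um",
        "beat.min_separation_s": "min_beat_separation_s",
        "beat.histogram_bins": "histogram_bins",
    }

    def __post_init__(self) -> None:
        for name in ("pillar_diameter_um", "pillar_length_um", "youngs_modulus_mpa",
                     "pitch_um", "pixel_size_um", "frame_rate_fps",
                     "expected_radius_px"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.reference_method not in ("percentile", "fixed-frame", "rolling"):
            raise ConfigError(
                f"unknown reference_method {self.reference_method!r}"
            )

    # ------------------------------------------------------------------
    @property
    def geometry(self) -> PillarGeometry:
        return PillarGeometry(self.pillar_diameter_um, self.pillar_length_um)

    @property
    def material(self) -> ElasticMaterial:
        return ElasticMaterial(self.youngs_modulus_mpa)

    def spring_constant(self) -> SpringConstant:
        """Effective stiffness: explicit override wins over the beam formula."""
        if self.spring_constant_n_per_m is not None:
            return SpringConstant(self.spring_constant_n_per_m)
        return spring_constant(self.geometry, self.material)

    def effective_min_separation_px(self) -> float:
        if self.min_separation_px is not None:
            return self.min_separation_px
        return 0.8 * self.pitch_um / self.pixel_size_um

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("provenance")
        return d

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.to_dict(), "provenance": self.provenance},
            indent=2, sort_keys=True,
        )

    def content_hash(self) -> str:
        """Stable hash of the effective parameter values (not provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_mapping(cls, mapping: dict, *, source: str | None = None,
                     overrides: dict | None = None) -> "AnalysisConfig":
        kwargs = {}
        for key, value in mapping.items():
            if key not in cls._KEYMAP:
                raise ConfigError(f"unknown config key {key!r}")
            kwargs[cls._KEYMAP[key]] = value
        if overrides:
            kwargs.update(overrides)
        field_types = {f.name: f.type for f in fields(cls)}
        coerced = {}
        for name, value in kwargs.items():
            if name == "invert" and isinstance(value, str):
                value = value.lower() in ("1", "true", "yes")
            elif name == "reference_method":
                value = str(value)
            elif isinstance(value, str):
                value = float(value)
            coerced[name] = value
        cfg = cls(**coerced)
        cfg.provenance = {"source": source, "overrides": sorted(overrides or {})}
        return cfg


def load_config(path=None, **overrides) -> AnalysisConfig:
    """Load a flat key/value or JSON config file; missing path = defaults.

    Keyword arguments override file values; both are recorded in the
    config's provenance.
    """
    mapping: dict = {}
    source = None
    if path is not None:
        path = Path(path)
        source = str(path)
        text = path.read_text()
        if path.suffix == ".json":
            flat = json.loads(text)
            if not isinstance(flat, dict):
                raise ConfigError(f"{path}: JSON config must be an object")
            mapping = flat
        else:
            for lineno, raw in enumerate(text.splitlines(), start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                for sep in ("=", ":"):
                    if sep in line:
                        key, _, value = line.partition(sep)
                        mapping[key.strip()] = value.strip()
                        break
                else:
                    raise ConfigError(f"{path}:{lineno}: cannot parse {raw!r}")
    return AnalysisConfig.from_mapping(mapping, source=source, overrides=overrides)
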