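"""Run configuration: TOML-backed settings for the end-to-end pipelines.

All physical lengths are in mm.  A seed is mandatory whenever any
stochastic element (characterization patterns, noise) is enabled, so every
pipeline run is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

from .phantoms import GearSpec, VesselPhantomSpec

__all__ = ["RunConfig", "MediumConfig", "CharacterizationConfig", "TomoConfig",
           "EvalConfig", "PhantomConfig"]


@dataclass
class PhantomConfig:
    kind: str = "gear"  # gear | vascular | stl
    pitch: float = 0.0625
    height: float = 2.0
    stl_path: str | None = None
    gear: dict = field(default_factory=dict)
    vascular: dict = field(default_factory=dict)

    def gear_spec(self) -> GearSpec:
        return GearSpec(height=self.height, **self.gear)

    def vascular_spec(self) -> VesselPhantomSpec:
        return VesselPhantomSpec(height=self.height, **self.vascular)


@dataclass
class MediumConfig:
    """Demo medium: l_s from the acrylate case; the in-plane loss length
    l_a folds together true absorption and wide-angle scattering out of the
    printing plane; sigma0/alpha describe the surviving forward halo."""

    l_s: float = 6.1
    sigma0: float = 0.1
    alpha: float = 0.3
    l_a: float = 5.0
    ballistic_only: bool = False

    def __post_init__(self) -> None:
        self.l_a = float(self.l_a)  # accepts "inf" from TOML


@dataclass
class CharacterizationConfig:
    pattern_count: int = 100
    noise_sigma: float = 0.0
    eps: float = 1e-3
    c_max: float = 10.0
    window: str = "hann"
    # amplitude-only mode: fit an attenuation length and correct in real
    # space instead of the frequency mask (never both)
    amplitude_only: bool = False


@dataclass
class TomoConfig:
    n_angles: int = 360
    iterations: int = 30
    step: float | None = None
    tolerance: float = 1e-4
    depth_bins: int = 16
    quantize: bool = False


@dataclass
class EvalConfig:
    n_thresholds: int = 256
    translations: tuple[int, ...] = (-2, -1, 0, 1, 2)
    rotations_deg: tuple[float, ...] = (-4.0, -2.0, 0.0, 2.0, 4.0)
    scales: tuple[float, ...] = (0.98, 1.0, 1.02)


@dataclass
class RunConfig:
    seed: int = 0
    vial_inner_diameter: float = 16.0
    output_dir: str = "scatvam_out"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    medium: MediumConfig = field(default_factory=MediumConfig)
    characterization: CharacterizationConfig = field(
        default_factory=CharacterizationConfig
    )
    tomo: TomoConfig = field(default_factory=TomoConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    @classmethod
    def from_toml(cls, path: str | Path, overrides: dict | None = None) -> "RunConfig":
        """Load a TOML config; ``overrides`` (flat ``section.key`` -> value)
        take precedence over file keys."""
        raw = tomllib.loads(Path(path).read_text())
        return cls.from_dict(raw, overrides)

    @classmethod
    def from_dict(cls, raw: dict, overrides: dict | None = None) -> "RunConfig":
        raw = {k: (dict(v) if isinstance(v, dict) else v) for k, v in raw.items()}
        for key, value in (overrides or {}).items():
            if value is None:
                continue
            if "." in key:
                section, name = key.split(".", 1)
                raw.setdefault(section, {})[name] = value
            else:
                raw[key] = value
        sections = {
            "phantom": PhantomConfig,
            "medium": MediumConfig,
            "characterization": CharacterizationConfig,
            "tomo": TomoConfig,
            "evaluation": EvalConfig,
        }
        kwargs: dict = {}
        for name, klass in sections.items():
            sub = raw.pop(name, {})
            if name == "evaluation":
                for tup in ("translations", "rotations_deg", "scales"):
                    if tup in sub:
                        sub[tup] = tuple(sub[tup])
            kwargs[name] = klass(**sub)
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the scientific configuration (for provenance
        records); the output location does not affect the digest."""
        payload = self.to_dict()
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
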