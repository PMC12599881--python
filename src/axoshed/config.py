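"""Scene configuration for the synthetic optic-nerve generator.

A :class:`SceneConfig` fixes every parameter of a simulated imaging session:
nerve and axon geometry, the movement-state mixture of axonal cargo
(mitochondria / OPTN puncta), transport speed distributions, the per-state
probability that a mitochondrion carries the partner-channel signal, how much
signal sits outside the axons and where, protrusion statistics, and the
optics/noise model.  Defaults follow the measured baseline of healthy
retinal-ganglion-cell axons: about half of axonal mitochondria are
stationary with a quarter moving in each direction, and anterograde /
retrograde movers average 0.63 and 0.78 um/s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["SceneConfig", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a scene or analysis configuration is invalid."""


def _default_coupling() -> dict:
    # probability that a mito-channel particle carries partner (OPTN) signal,
    # per movement state; stationary-enriched as in wild-type nerves
    return {"stationary": 0.6, "anterograde": 0.2, "retrograde": 0.2}


def _default_noise() -> dict:
    # scaled-Poisson shot noise plus Gaussian read noise; with the default
    # spot amplitude this gives SNR ~ 5 at spot peaks
    return {"gaussian_sd": 3.0, "poisson_scale": 1.0}


@dataclass
class SceneConfig:
    # geometry
    nerve_diameter_um: float = 30.0
    field_length_um: float = 250.0
    n_axons: int = 20
    axon_diameter_um: float = 1.0
    pixel_size_um: float = 0.2

    # time-lapse sampling (1 min at 1 Hz)
    frame_interval_s: float = 1.0
    n_frames: int = 60
    z_step_um: float = 1.0

    # particle population
    n_particles: int = 500
    state_fractions: tuple = (0.5, 0.25, 0.25)  # stationary, antero, retro
    speed_mean_antero_um_s: float = 0.63
    speed_mean_retro_um_s: float = 0.78
    speed_sd_um_s: float = 0.15
    stationary_jitter_um: float = 0.05
    coloc_coupling: dict = field(default_factory=_default_coupling)

    # extra-axonal signal (z-stack mode)
    extra_axonal_fraction: float = 0.15
    surface_share_of_outside: float = 0.239
    zstack_axon_diameter_um: float = 3.0
    zstack_n_axons: int = 6
    zstack_length_um: float = 60.0

    # protrusions / dystrophies
    protrusion_density_per_100um: float = 0.47
    protrusion_mito_prob: float = 0.603
    pinch_prob_per_interval: float = 0.1

    # optics and noise
    psf_sigma_um: float = 0.25
    spot_amplitude: float = 36.0
    noise_model: dict = field(default_factory=_default_noise)
    drift_per_frame_px: tuple = (0.0, 0.0)

    seed: int = 0

    def __post_init__(self) -> None:
        self.state_fractions = tuple(float(f) for f in self.state_fractions)
        self.drift_per_frame_px = tuple(float(d) for d in self.drift_per_frame_px)
        if len(self.state_fractions) != 3:
            raise ConfigurationError("state_fractions must have 3 entries")
        if any(f < 0 for f in self.state_fractions):
            raise ConfigurationError("state_fractions must be non-negative")
        if abs(sum(self.state_fractions) - 1.0) > 1e-12:
            raise ConfigurationError(
                f"state_fractions must sum to 1, got {sum(self.state_fractions)!r}"
            )
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        for name in (
            "nerve_diameter_um", "field_length_um", "axon_diameter_um",
            "pixel_size_um", "frame_interval_s", "z_step_um",
            "speed_mean_antero_um_s", "speed_mean_retro_um_s",
            "psf_sigma_um", "spot_amplitude",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("speed_sd_um_s", "stationary_jitter_um",
                     "protrusion_density_per_100um"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("extra_axonal_fraction", "surface_share_of_outside",
                     "protrusion_mito_prob", "pinch_prob_per_interval"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for state, p in self.coloc_coupling.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"coloc_coupling[{state!r}] must be in [0, 1], got {p}"
                )

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["state_fractions"] = list(self.state_fractions)
        d["drift_per_frame_px"] = list(self.drift_per_frame_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kw) -> "SceneConfig":
        return dataclasses.replace(self, **kw)
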