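"""Configuration dataclasses shared across the simulation and analysis stages.

All spatial quantities are in pixels with a 0-based, top-left origin
(x rightward, y downward); intensities are in camera counts; photon rates
are expected photon counts per exposure.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "MixtureConfig",
    "MobilityConfig",
    "PopulationConfig",
    "OpticsConfig",
    "KineticsConfig",
    "DetectParams",
    "ConfigError",
    "child_rng",
]


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def child_rng(seed: int, *tags: object) -> np.random.Generator:
    """Derive an independent generator from a root seed and a label path.

    The same (seed, tags) always yields the same stream; different stage /
    well / channel / timepoint labels yield decorrelated streams.  Labels are
    hashed with CRC32 so the derivation is stable across interpreter runs.
    """
    words = [int(seed) & 0x7FFFFFFF]
    for tag in tags:
        words.append(zlib.crc32(str(tag).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(words))


@dataclass(frozen=True)
class MixtureConfig:
    """Treatment-response mixture of a cell population.

    A *responder* suppresses its reporter output between the two imaging
    sessions (log fold-change drawn from ``responder_logfc``); a
    *non-responder* maintains or increases it (``nonresponder_logfc``).
    A fraction ``p_deep_given_responder`` of responders shut the reporter
    off essentially completely (``deep_logfc``), which is what produces the
    "no detectable signal" cells below the limit of detection.
    Log fold-changes are natural logs.
    """

    p_responder: float = 0.5
    responder_logfc: Tuple[float, float] = (-1.6, 0.3)  # (mean, sd)
    nonresponder_logfc: Tuple[float, float] = (0.8, 0.25)
    p_deep_given_responder: float = 0.0
    deep_logfc: Tuple[float, float] = (-9.2, 0.5)

    def validate(self) -> None:
        if not 0.0 <= self.p_responder <= 1.0:
            raise ConfigError(f"p_responder must be in [0,1], got {self.p_responder}")
        if not 0.0 <= self.p_deep_given_responder <= 1.0:
            raise ConfigError("p_deep_given_responder must be in [0,1]")
        for name in ("responder_logfc", "nonresponder_logfc", "deep_logfc"):
            mu, sd = getattr(self, name)
            if sd < 0:
                raise ConfigError(f"{name} sd must be >= 0, got {sd}")


@dataclass(frozen=True)
class MobilityConfig:
    """Between-session cell fate probabilities and positional jitter.

    ``p_lost`` cells vanish before the second imaging; ``p_displaced`` cells
    re-attach at an unrelated position; the remainder stay put up to an
    isotropic Gaussian jitter (sd ``jitter_sd``, truncated at the tracking
    match radius so a retained cell is trackable by construction).
    """

    p_lost: float = 0.0
    p_displaced: float = 0.0
    jitter_sd: float = 2.0
    match_radius: float = 15.0

    def validate(self) -> None:
        if not 0.0 <= self.p_lost <= 1.0 or not 0.0 <= self.p_displaced <= 1.0:
            raise ConfigError("fate probabilities must be in [0,1]")
        if self.p_lost + self.p_displaced > 1.0 + 1e-12:
            raise ConfigError(
                f"p_lost + p_displaced must be <= 1, got {self.p_lost + self.p_displaced}"
            )
        if self.jitter_sd < 0:
            raise ConfigError("jitter_sd must be >= 0")
        if self.match_radius <= 0:
            raise ConfigError("match_radius must be > 0")


@dataclass(frozen=True)
class PopulationConfig:
    """Ground-truth population of luciferase-expressing cells in one well."""

    n_cells: int = 2000
    field_size: Tuple[int, int] = (4096, 4096)  # (width, height)
    min_separation: float = 20.0
    margin: float = 30.0  # keeps every aperture + background annulus in-frame
    intensity_lognormal: Tuple[float, float] = (9.9, 0.5)  # (mu, sigma) of ln rate
    gfp_lognormal: Tuple[float, float] = (10.3, 0.3)
    mixture: MixtureConfig = field(default_factory=MixtureConfig)
    mobility: MobilityConfig = field(default_factory=MobilityConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ConfigError("n_cells must be >= 0")
        if self.intensity_lognormal[1] < 0 or self.gfp_lognormal[1] < 0:
            raise ConfigError("lognormal sigma must be >= 0")
        if self.min_separation < 0 or self.margin < 0:
            raise ConfigError("min_separation and margin must be >= 0")
        w, h = self.field_size
        usable_w = w - 2 * self.margin
        usable_h = h - 2 * self.margin
        if self.n_cells > 0 and (usable_w <= 0 or usable_h <= 0):
            raise ConfigError("field smaller than twice the margin")
        # hard-disc packing sanity bound: rejection sampling is hopeless past
        # ~30% packing fraction of the usable area
        if self.n_cells > 0:
            disc_area = np.pi * (self.min_separation / 2.0) ** 2
            if self.n_cells * disc_area > 0.30 * usable_w * usable_h:
                raise ConfigError(
                    f"cannot place {self.n_cells} cells at min_separation "
                    f"{self.min_separation} in a {w}x{h} field"
                )
        self.mixture.validate()
        self.mobility.validate()


@dataclass(frozen=True)
class OpticsConfig:
    """EM-CCD imaging model.

    ``background_level`` is the post-gain mean background in counts; photon
    shot noise (Poisson) is multiplied by ``em_gain`` and Gaussian read noise
    of sd ``read_noise_sd`` is added.  The EM excess-noise factor is folded
    into ``read_noise_sd`` rather than modelled as a gain cascade.
    ``exposure_s`` is carried as metadata (rates are already per exposure).
    """

    psf_sigma: float = 1.5
    cell_radius: float = 3.0
    background_level: float = 100.0
    read_noise_sd: float = 3.0
    em_gain: float = 1.0
    exposure_s: float = 20.0
    bit_depth: int = 16
    saturation: int = 65535

    def validate(self) -> None:
        if self.psf_sigma <= 0:
            raise ConfigError("psf_sigma must be > 0")
        if self.cell_radius <= 0:
            raise ConfigError("cell_radius must be > 0")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ConfigError("background_level and read_noise_sd must be >= 0")
        if self.em_gain < 1:
            raise ConfigError("em_gain must be >= 1")
        if self.saturation <= 0:
            raise ConfigError("saturation must be > 0")

    @property
    def background_pixel_sd(self) -> float:
        """Theoretical per-pixel sd of a background pixel (counts)."""
        return float(
            np.sqrt(self.em_gain * self.background_level + self.read_noise_sd**2)
        )


@dataclass(frozen=True)
class KineticsConfig:
    """Exponential signal-decay kinetics of the luciferin time course."""

    decay_rate: float = 0.0  # per minute
    t_start: float = 30.0  # minutes after substrate addition
    t_end: float = 230.0
    dt: float = 10.0

    def validate(self) -> None:
        if self.decay_rate < 0:
            raise ConfigError("decay_rate must be >= 0")
        if not self.t_start < self.t_end:
            raise ConfigError("t_start must be < t_end")
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")


@dataclass(frozen=True)
class DetectParams:
    """Detection and aperture-photometry parameters.

    The default aperture radius, 3*psf_sigma + cell_radius, captures >99% of
    the flux of a PSF-blurred disc for the default optics.
    """

    smoothing_sigma: float = 1.5
    threshold_k: float = 5.0
    min_peak_distance: int = 8
    aperture_radius: float = 7.5
    annulus: Tuple[float, float] = (10.0, 25.0)

    def validate(self) -> None:
        if self.threshold_k <= 0:
            raise ConfigError("threshold_k must be > 0")
        if not (self.aperture_radius < self.annulus[0] < self.annulus[1]):
            raise ConfigError(
                "require aperture_radius < annulus inner < annulus outer"
            )
        if self.min_peak_distance < 1:
            raise ConfigError("min_peak_distance must be >= 1")

    @classmethod
    def for_optics(cls, optics: OpticsConfig, **kwargs) -> "DetectParams":
        """Build parameters matched to an optical model."""
        r = 3.0 * optics.psf_sigma + optics.cell_radius
        # the wide annulus keeps the background-estimate noise (which enters
        # the aperture sum multiplied by the aperture area) well below the
        # summed pixel noise
        defaults = dict(
            smoothing_sigma=optics.psf_sigma,
            aperture_radius=r,
            annulus=(r + 2.5, r + 17.5),
        )
        defaults.update(kwargs)
        return cls(**defaults)


def config_to_dict(cfg) -> dict:
    """Plain-dict view of any config dataclass (for manifests / YAML)."""
    return asdict(cfg)
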