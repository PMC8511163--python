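"""Optical and simulation configuration objects.

Coordinate convention used everywhere in this package: 0-based pixel grid,
origin at the top-left corner, x increasing rightward, y increasing downward,
continuous positions in micrometres.
"""

from __future__ import annotations

import dataclasses
import math


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclasses.dataclass(frozen=True)
class OpticsModel:
    """TIRF imaging model for rendering and calibration.

    Parameters
    ----------
    pixel_size : float
        Camera pixel size in the sample plane, μm/px.
    psf_sigma : float
        Gaussian point-spread-function standard deviation, μm.
    exposure : float
        Camera exposure per frame, s.  Must not exceed ``frame_interval``.
    frame_interval : float
        Time between successive frame starts, s.
    evanescent_depth : float
        1/e decay depth of the evanescent excitation field, nm.
    gain : float
        Counts per detected photon.
    read_noise_sd : float
        Gaussian read noise standard deviation, counts.
    photon_rate : float
        Detected photons per second per fluorophore at height 0.
    background_rate : float
        Background photons per μm² per second (autofluorescence and
        scattered excitation light).
    offset : float
        Constant camera offset added to every pixel, counts.
    """

    pixel_size: float = 0.1
    psf_sigma: float = 0.15
    exposure: float = 0.5
    frame_interval: float = 0.5
    evanescent_depth: float = 100.0
    gain: float = 1.0
    read_noise_sd: float = 2.0
    photon_rate: float = 2.0e4
    background_rate: float = 100.0
    offset: float = 100.0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "psf_sigma", "exposure", "frame_interval",
                     "evanescent_depth", "gain", "photon_rate"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v > 0, f"{name} must be finite and > 0, got {v}")
        for name in ("read_noise_sd", "background_rate", "offset"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0, f"{name} must be finite and >= 0, got {v}")
        _require(self.exposure <= self.frame_interval + 1e-12,
                 "exposure must not exceed frame_interval")


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Ground-truth simulation parameters for ligands diffusing on a bilayer.

    A molecule alternates between a fast freely diffusing state
    (``d_free``) and a slow receptor-bound state (``d_bound``); switching
    free→bound occurs at rate ``k_on_app`` and bound→free at rate
    ``1/tau_off_true``.  Photobleaching is single-step with exponential
    clock ``tau_bleach_true`` that advances only while the molecule is
    illuminated.  Fluorophore heights above the bilayer (set by the DNA
    tether) are drawn on ``[0, fluorophore_height_max]`` nm.
    """

    box_size: float = 25.0           # μm, square field, reflecting walls
    density: float = 0.06            # molecules/μm²
    d_free: float = 2.5              # μm²/s
    d_bound: float = 0.01            # μm²/s
    k_on_app: float = 0.0            # 1/s
    tau_off_true: float = math.inf   # s
    tau_bleach_true: float = math.inf  # s of illuminated time
    fluorophore_height_max: float = 0.0  # nm; 0 → all molecules at height 0
    height_mean: float | None = None     # nm; mean of truncated-normal heights
    n_frames: int = 100
    initial_bound_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        _require(math.isfinite(self.box_size) and self.box_size > 0, "box_size must be > 0")
        _require(self.density >= 0, "density must be >= 0")
        _require(math.isfinite(self.d_free) and self.d_free >= 0, "d_free must be >= 0")
        _require(math.isfinite(self.d_bound) and self.d_bound >= 0, "d_bound must be >= 0")
        _require(self.d_bound <= self.d_free, "d_bound must not exceed d_free")
        _require(self.k_on_app >= 0, "k_on_app must be >= 0")
        _require(self.tau_off_true > 0, "tau_off_true must be > 0")
        _require(self.tau_bleach_true > 0, "tau_bleach_true must be > 0")
        _require(self.fluorophore_height_max >= 0, "fluorophore_height_max must be >= 0")
        _require(self.n_frames >= 1, "n_frames must be >= 1")
        _require(0.0 <= self.initial_bound_fraction <= 1.0,
                 "initial_bound_fraction must be in [0, 1]")
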