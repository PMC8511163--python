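"""Render ground-truth trajectories into TIRF image stacks.

Each unbleached molecule contributes a pixel-integrated Gaussian PSF at
every trajectory substep inside the exposure window, so fast molecules
produce motion-blurred streaks while slow (receptor-bound) molecules
produce sharp spots — the contrast the long-exposure "bound-only" imaging
strategy exploits.  Emission is attenuated by the evanescent excitation
field, ``exp(-height / evanescent_depth)``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.special import erf

from .config import OpticsModel
from .synthetic import GroundTruth, STATE_BLEACHED

logger = logging.getLogger(__name__)

_SQRT2 = math.sqrt(2.0)


def _pixel_gauss_1d(centers_px: np.ndarray, lo: int, hi: int, sigma_px: float) -> np.ndarray:
    """Integral of a unit Gaussian over pixels [lo, hi) for each center.

    Returns array (n_centers, hi - lo); pixel i covers [i, i+1) in
    continuous pixel coordinates.
    """
    edges = np.arange(lo, hi + 1, dtype=float)
    z = (edges[None, :] - centers_px[:, None]) / (sigma_px * _SQRT2)
    c = 0.5 * (1.0 + erf(z))
    return c[:, 1:] - c[:, :-1]


def render_movie(truth: GroundTruth,
                 optics: OpticsModel,
                 noise: bool = True,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render every frame of a ground-truth simulation.

    Returns a float array ``(n_frames, ny, nx)`` of camera counts.  With
    ``noise=True``, photon shot noise (Poisson), gain, camera offset and
    Gaussian read noise are applied; with ``noise=False`` the expectation
    image is returned (no offset, no background), which is convenient for
    analytic checks.

    Requires ≥10 trajectory substeps per exposure for a converged motion
    blur integral.  Molecules outside the field contribute nothing and are
    logged once.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    dt_sub = truth.frame_interval / truth.substeps_per_frame
    sub_per_exp = int(round(optics.exposure / dt_sub))
    if sub_per_exp < 10:
        raise ValueError(
            f"need >=10 substeps per exposure for motion blur, got {sub_per_exp}; "
            "increase substeps_per_frame in the simulation")
    n_frames = truth.n_frames
    n_px = int(round(truth.config.box_size / optics.pixel_size))
    sigma_px = optics.psf_sigma / optics.pixel_size
    half_w = max(3, int(math.ceil(4.0 * sigma_px)))
    photons_per_sub = optics.photon_rate * dt_sub
    atten = np.exp(-truth.height_nm / optics.evanescent_depth)
    bg_photons = optics.background_rate * optics.exposure * optics.pixel_size ** 2

    movie = np.zeros((n_frames, n_px, n_px))
    clipped_any = False
    for f in range(n_frames):
        i0 = f * truth.substeps_per_frame
        sub = slice(i0, i0 + sub_per_exp)
        img = np.zeros((n_px, n_px))
        for m in range(truth.n_molecules):
            alive = truth.state[m, sub] != STATE_BLEACHED
            if not alive.any():
                continue
            xs = truth.x[m, sub][alive] / optics.pixel_size
            ys = truth.y[m, sub][alive] / optics.pixel_size
            cx, cy = xs.mean(), ys.mean()
            if not (0 <= cx < n_px and 0 <= cy < n_px):
                clipped_any = True
                continue
            x_lo = max(0, int(xs.min()) - half_w)
            x_hi = min(n_px, int(xs.max()) + half_w + 1)
            y_lo = max(0, int(ys.min()) - half_w)
            y_hi = min(n_px, int(ys.max()) + half_w + 1)
            gx = _pixel_gauss_1d(xs, x_lo, x_hi, sigma_px)   # (S, W)
            gy = _pixel_gauss_1d(ys, y_lo, y_hi, sigma_px)
            patch = np.einsum("sy,sx->yx", gy, gx)
            img[y_lo:y_hi, x_lo:x_hi] += photons_per_sub * atten[m] * patch
        if noise:
            img = optics.gain * rng.poisson(img + bg_photons).astype(float)
            img += optics.offset + rng.normal(0.0, optics.read_noise_sd, img.shape)
        movie[f] = img
    if clipped_any:
        logger.info("some molecules were outside the field and were clipped")
    return movie
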