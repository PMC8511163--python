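"""Forward simulation of every input the analysis pipeline consumes.

The generators here produce, with known ground truth: Brownian trajectories
of membrane-tethered ligands with a slow receptor-bound state and
single-step photobleaching; single-particle intensity traces; cell
activation populations following a Hill dose-response; and per-cell
binding-event / condensate streams.  Rendering of trajectories into TIRF
movies lives in :mod:`fabtirf.render`.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .config import OpticsModel, SimConfig

STATE_FREE = 0
STATE_BOUND = 1
STATE_BLEACHED = 2

STATE_NAMES = {STATE_FREE: "free", STATE_BOUND: "bound", STATE_BLEACHED: "bleached"}


@dataclasses.dataclass
class GroundTruth:
    """Sub-frame-resolution trajectories with per-molecule state.

    Arrays are indexed ``[molecule, substep]``.  ``state`` uses the codes
    ``STATE_FREE``, ``STATE_BOUND``, ``STATE_BLEACHED``; bleached is
    absorbing.  ``height_nm`` is the (static) fluorophore height above the
    bilayer set by the DNA tether.  ``dwell_durations_s`` lists the true
    durations of completed bound intervals.
    """

    config: SimConfig
    t: np.ndarray              # (n_sub,) substep times, s
    x: np.ndarray              # (n_mol, n_sub) μm
    y: np.ndarray              # (n_mol, n_sub) μm
    height_nm: np.ndarray      # (n_mol,)
    state: np.ndarray          # (n_mol, n_sub) uint8
    substeps_per_frame: int
    frame_interval: float      # s
    dwell_durations_s: list[float]

    @property
    def n_molecules(self) -> int:
        return self.x.shape[0]

    @property
    def n_frames(self) -> int:
        return self.x.shape[1] // self.substeps_per_frame

    def frame_table(self) -> pd.DataFrame:
        """Per-frame snapshot (state and position at each frame start)."""
        idx = np.arange(self.n_frames) * self.substeps_per_frame
        rows = []
        for m in range(self.n_molecules):
            rows.append(pd.DataFrame({
                "molecule_id": m,
                "frame": np.arange(self.n_frames),
                "t_s": self.t[idx],
                "x_um": self.x[m, idx],
                "y_um": self.y[m, idx],
                "height_nm": self.height_nm[m],
                "state": [STATE_NAMES[s] for s in self.state[m, idx]],
            }))
        return pd.concat(rows, ignore_index=True)

    def true_bound_fraction(self) -> float:
        """Fraction of unbleached molecules bound at the first frame."""
        s0 = self.state[:, 0]
        alive = s0 != STATE_BLEACHED
        if not alive.any():
            return float("nan")
        return float((s0[alive] == STATE_BOUND).mean())


def _reflect(pos: np.ndarray, box: float) -> np.ndarray:
    """Fold positions back into [0, box] by mirror reflection."""
    period = 2.0 * box
    p = np.mod(pos, period)
    return np.where(p > box, period - p, p)


def sample_fluorophore_heights(n: int, height_max_nm: float,
                               mean_nm: float | None,
                               rng: np.random.Generator) -> np.ndarray:
    """Draw static fluorophore heights on [0, height_max_nm].

    Truncated normal with the given mean (default half the contour length)
    and SD of a quarter of the contour length — a simple stand-in for the
    worm-like-chain height distribution of a flexible poly(dT) tether that
    preserves the monotone mean-height ordering between tether lengths.
    """
    if height_max_nm == 0:
        return np.zeros(n)
    mu = height_max_nm / 2.0 if mean_nm is None else mean_nm
    sd = height_max_nm / 4.0
    h = rng.normal(mu, sd, size=4 * n + 16)
    h = h[(h >= 0) & (h <= height_max_nm)]
    while h.size < n:
        extra = rng.normal(mu, sd, size=4 * n)
        h = np.concatenate([h, extra[(extra >= 0) & (extra <= height_max_nm)]])
    return h[:n]


def simulate_trajectories(cfg: SimConfig,
                          substeps_per_frame: int = 10,
                          frame_interval: float = 0.5,
                          illuminated_fraction: float = 1.0,
                          n_molecules: int | None = None,
                          rng: np.random.Generator | None = None) -> GroundTruth:
    """Simulate 2-D Brownian trajectories with binding and bleaching.

    Free-state displacements per substep ``dt`` are Gaussian with per-axis
    variance ``2 * d_free * dt`` (bound state likewise with ``d_bound``);
    boundaries are reflecting.  Free→bound switching occurs at rate
    ``k_on_app`` and bound→free at ``1/tau_off_true``.  The bleaching clock
    (mean ``tau_bleach_true``) advances only during the illuminated fraction
    of each frame, i.e. while ``t mod frame_interval < illuminated_fraction
    * frame_interval``.

    Parameters not in ``cfg``: ``substeps_per_frame`` sets the temporal
    resolution (rendering requires ≥10 substeps per exposure),
    ``n_molecules`` overrides the Poisson draw from ``cfg.density``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    dt = frame_interval / substeps_per_frame
    n_sub = cfg.n_frames * substeps_per_frame
    if n_molecules is None:
        n_mol = int(rng.poisson(cfg.density * cfg.box_size ** 2))
    else:
        n_mol = int(n_molecules)
    t = np.arange(n_sub) * dt

    x = np.empty((n_mol, n_sub))
    y = np.empty((n_mol, n_sub))
    state = np.empty((n_mol, n_sub), dtype=np.uint8)
    x[:, 0] = rng.uniform(0, cfg.box_size, n_mol)
    y[:, 0] = rng.uniform(0, cfg.box_size, n_mol)
    bound0 = rng.random(n_mol) < cfg.initial_bound_fraction
    state[:, 0] = np.where(bound0, STATE_BOUND, STATE_FREE)
    heights = sample_fluorophore_heights(
        n_mol, cfg.fluorophore_height_max, cfg.height_mean, rng)

    p_bind = -np.expm1(-cfg.k_on_app * dt)
    p_unbind = -np.expm1(-dt / cfg.tau_off_true) if np.isfinite(cfg.tau_off_true) else 0.0
    p_bleach = -np.expm1(-dt / cfg.tau_bleach_true) if np.isfinite(cfg.tau_bleach_true) else 0.0

    sd_free = math.sqrt(2.0 * cfg.d_free * dt)
    sd_bound = math.sqrt(2.0 * cfg.d_bound * dt)

    bind_start = np.where(bound0, 0.0, np.nan)  # time current bound interval began
    dwells: list[float] = []
    illum_cut = illuminated_fraction * frame_interval

    for i in range(1, n_sub):
        prev = state[:, i - 1]
        cur = prev.copy()
        free = prev == STATE_FREE
        bound = prev == STATE_BOUND
        u = rng.random(n_mol)
        # binding / unbinding
        newly_bound = free & (u < p_bind)
        newly_free = bound & (u < p_unbind)
        cur[newly_bound] = STATE_BOUND
        cur[newly_free] = STATE_FREE
        bind_start[newly_bound] = t[i]
        for m in np.nonzero(newly_free)[0]:
            dwells.append(t[i] - bind_start[m])
            bind_start[m] = np.nan
        # bleaching (absorbing; clock only while illuminated)
        if p_bleach > 0.0 and (t[i - 1] % frame_interval) < illum_cut:
            zap = (prev != STATE_BLEACHED) & (rng.random(n_mol) < p_bleach)
            cur[zap] = STATE_BLEACHED
        state[:, i] = cur
        # displacement: bleached molecules keep diffusing in their last
        # mobility state but are dark; use free-state mobility for them
        sd = np.where(bound | newly_bound, sd_bound, sd_free)
        sd[newly_free] = sd_free
        x[:, i] = _reflect(x[:, i - 1] + rng.normal(0.0, 1.0, n_mol) * sd, cfg.box_size)
        y[:, i] = _reflect(y[:, i - 1] + rng.normal(0.0, 1.0, n_mol) * sd, cfg.box_size)

    return GroundTruth(config=cfg, t=t, x=x, y=y, height_nm=heights, state=state,
                       substeps_per_frame=substeps_per_frame,
                       frame_interval=frame_interval, dwell_durations_s=dwells)


def simulate_intensity_traces(n_traces: int,
                              n_fluorophores: int,
                              tau_bleach: float,
                              frame_interval: float,
                              n_frames: int,
                              level_per_fluorophore: float = 1000.0,
                              snr: float = 5.0,
                              background: float = 0.0,
                              rng: np.random.Generator | None = None,
                              require_complete: bool = True,
                              min_visible_frames: int = 5,
                              min_step_separation_frames: int = 0) -> pd.DataFrame:
    """Simulate single-particle intensity traces with stepwise bleaching.

    Each trace starts with ``n_fluorophores`` emitters, each contributing
    ``level_per_fluorophore`` counts; every emitter bleaches independently
    at an exponential time with mean ``tau_bleach``.  Gaussian noise of SD
    ``level_per_fluorophore / snr`` is added.  With ``require_complete``,
    bleach times are redrawn until all emitters bleach before the trace
    ends (traces must reach background for step counting) and no emitter
    bleaches within the first ``min_visible_frames`` frames — mirroring
    the selection of real trace populations, where a particle must be
    detected and tracked for several frames before its trace is analyzed
    at all.  ``min_step_separation_frames`` optionally conditions
    multi-emitter traces on bleach events separated by at least that many
    frames (two drops inside one or two frames are below any change-point
    detector's temporal resolution and merge into a single taller step).

    Returns a long-format frame with columns ``trace_id, t_s, intensity``
    plus ``n_true_steps`` (constant per trace).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    t = np.arange(n_frames) * frame_interval
    t_max = t[-1]
    noise_sd = level_per_fluorophore / snr
    frames = []
    for k in range(n_traces):
        bt = rng.exponential(tau_bleach, n_fluorophores)
        if require_complete:
            t_min = min_visible_frames * frame_interval
            sep = min_step_separation_frames * frame_interval
            tries = 0
            while (bt.max() >= 0.9 * t_max or bt.min() < t_min
                   or (len(bt) > 1 and np.diff(np.sort(bt)).min() < sep)):
                bt = rng.exponential(tau_bleach, n_fluorophores)
                tries += 1
                if tries > 1000:
                    raise RuntimeError("bleach horizon too short for tau_bleach")
        n_alive = (t[None, :] < bt[:, None]).sum(axis=0)
        inten = background + n_alive * level_per_fluorophore \
            + rng.normal(0.0, noise_sd, n_frames)
        frames.append(pd.DataFrame({"trace_id": k, "t_s": t, "intensity": inten,
                                    "n_true_steps": n_fluorophores}))
    return pd.concat(frames, ignore_index=True)


def simulate_activation_population(densities: list[float] | np.ndarray,
                                   ec50: float,
                                   hill: float,
                                   max_resp: float,
                                   n_cells: int,
                                   rng_seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Bernoulli cell-activation outcomes under a Hill dose-response.

    Each of ``n_cells`` cells at surface density ρ activates with
    probability ``max_resp * ρ^h / (ρ^h + EC50^h)``.  Returns columns
    ``density, cell_id, activated``.
    """
    densities = np.asarray(densities, dtype=float)
    if np.any(densities <= 0):
        raise ValueError("densities must be > 0")
    if hill <= 0:
        raise ValueError("hill must be > 0")
    if not (0.0 < max_resp <= 1.0):
        raise ValueError("max_resp must be in (0, 1]")
    if ec50 <= 0:
        raise ValueError("ec50 must be > 0")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    rows = []
    for rho in densities:
        p = max_resp * rho ** hill / (rho ** hill + ec50 ** hill)
        act = rng.random(n_cells) < p
        rows.append(pd.DataFrame({
            "density": rho, "cell_id": np.arange(n_cells), "activated": act}))
    return pd.concat(rows, ignore_index=True)


@dataclasses.dataclass
class CellEventStream:
    """Ground-truth binding events and condensates for one cell."""

    cell_id: int
    binding_events: pd.DataFrame   # t_s, x_um, y_um
    condensates: pd.DataFrame      # t_start_s, x_um, y_um, lifetime_frames, source_event


def simulate_event_streams(n_cells: int,
                           events_per_cell_mean: float,
                           p_condensate: float,
                           background_rate: float,
                           rng_seed: int | np.random.Generator = 0,
                           window_s: float = 120.0,
                           frame_interval_s: float = 2.0,
                           footprint_um: float = 10.0,
                           lag_mean_s: float = 4.0,
                           lag_max_s: float = 10.0,
                           colocalization_sd_um: float = 0.1) -> list[CellEventStream]:
    """Per-cell binding-event and LAT-condensate streams.

    Binding events are Poisson (mean ``events_per_cell_mean``) with uniform
    times in the observation window and uniform positions in a square
    footprint.  Each event independently spawns a condensate with
    probability ``p_condensate`` — appearing a few seconds later
    (exponential lag, mean ``lag_mean_s``, capped at ``lag_max_s``) within
    ``colocalization_sd_um`` of the event — that persists for ≥4 frames.
    Background condensates unrelated to binding are added as a Poisson
    count with mean ``background_rate`` per cell.
    """
    for name, p in (("p_condensate", p_condensate),):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    if background_rate < 0 or events_per_cell_mean < 0:
        raise ValueError("rates must be >= 0")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    cells = []
    for c in range(n_cells):
        n_ev = rng.poisson(events_per_cell_mean)
        ev = pd.DataFrame({
            "t_s": np.sort(rng.uniform(0.0, window_s, n_ev)),
            "x_um": rng.uniform(0.0, footprint_um, n_ev),
            "y_um": rng.uniform(0.0, footprint_um, n_ev),
        })
        cond_rows = []
        for i in range(n_ev):
            if rng.random() < p_condensate:
                lag = min(rng.exponential(lag_mean_s), lag_max_s)
                cond_rows.append({
                    "t_start_s": ev.t_s[i] + lag,
                    "x_um": ev.x_um[i] + rng.normal(0, colocalization_sd_um),
                    "y_um": ev.y_um[i] + rng.normal(0, colocalization_sd_um),
                    "lifetime_frames": 4 + int(rng.poisson(3)),
                    "source_event": i,
                })
        for _ in range(int(rng.poisson(background_rate))):
            cond_rows.append({
                "t_start_s": rng.uniform(0.0, window_s),
                "x_um": rng.uniform(0.0, footprint_um),
                "y_um": rng.uniform(0.0, footprint_um),
                "lifetime_frames": 4 + int(rng.poisson(3)),
                "source_event": -1,
            })
        cond = pd.DataFrame(cond_rows, columns=["t_start_s", "x_um", "y_um",
                                                "lifetime_frames", "source_event"])
        cells.append(CellEventStream(cell_id=c, binding_events=ev, condensates=cond))
    return cells


def simulate_dwell_events(n_events: int,
                          tau_off: float,
                          tau_bleach_illuminated: float,
                          lapse_s: float,
                          exposure_s: float = 0.5,
                          censor_time_s: float | None = None,
                          censor_sd_s: float = 0.0,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate observed binding-event durations on a frame lapse grid.

    True dwell times are exponential with mean ``tau_off``.  Photobleaching
    consumes illuminated time (``exposure_s`` per ``lapse_s`` of wall-clock
    time) with mean ``tau_bleach_illuminated``; a bleach before unbinding
    truncates the visible event and is indistinguishable from unbinding in
    the observation, exactly as in real data.  ``censor_time_s`` models
    tracking loss (e.g. centripetal transport): events still visible then
    are right-censored.  Events shorter than one lapse are unobserved and
    dropped.

    Returns columns ``duration_s`` (multiple of the lapse), ``censored``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    duty = exposure_s / lapse_s
    t_true = rng.exponential(tau_off, n_events)
    if np.isfinite(tau_bleach_illuminated):
        t_bleach = rng.exponential(tau_bleach_illuminated / duty, n_events)
    else:
        t_bleach = np.full(n_events, np.inf)
    visible = np.minimum(t_true, t_bleach)
    if censor_time_s is not None:
        c = np.maximum(rng.normal(censor_time_s, censor_sd_s, n_events), lapse_s)
        censored = visible > c
        obs = np.where(censored, c, visible)
    else:
        censored = np.zeros(n_events, dtype=bool)
        obs = visible
    k = np.floor(obs / lapse_s).astype(int)
    keep = k >= 1
    return pd.DataFrame({"duration_s": k[keep] * lapse_s,
                         "censored": censored[keep]})


def simulate_nfat_cell(shape: tuple[int, int] = (120, 120),
                       footprint_radius_px: int = 45,
                       nucleus_radius_px: int = 18,
                       background: float = 100.0,
                       cytosol_level: float = 300.0,
                       nucleus_to_cytosol: float = 2.0,
                       noise_sd: float = 5.0,
                       nucleus_offset_px: tuple[int, int] = (0, 0),
                       rng: np.random.Generator | None = None):
    """Render a two-compartment NFAT reporter cell image.

    Returns ``(image, footprint_mask, nucleus_mask)``.  Intensities are
    ``background`` outside the cell, ``background + cytosol_level`` in the
    cytosol and ``background + nucleus_to_cytosol * cytosol_level`` in the
    nucleus, plus Gaussian noise.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = shape[0] / 2.0, shape[1] / 2.0
    foot = (yy - cy) ** 2 + (xx - cx) ** 2 <= footprint_radius_px ** 2
    ny, nx = cy + nucleus_offset_px[0], cx + nucleus_offset_px[1]
    nuc = (yy - ny) ** 2 + (xx - nx) ** 2 <= nucleus_radius_px ** 2
    nuc &= foot
    img = np.full(shape, background, dtype=float)
    img[foot] = background + cytosol_level
    img[nuc] = background + nucleus_to_cytosol * cytosol_level
    img += rng.normal(0.0, noise_sd, shape)
    return img, foot, nuc


def render_condensate_movie(condensates: pd.DataFrame,
                            n_frames: int,
                            frame_interval_s: float = 2.0,
                            field_um: float = 10.0,
                            pixel_size_um: float = 0.1,
                            sigma_um: float = 0.3,
                            amplitude: float = 400.0,
                            background: float = 100.0,
                            noise_sd: float | None = None,
                            snr: float = 4.0,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """Render a LAT-eGFP-like movie of Gaussian condensate blobs.

    Each row of ``condensates`` (``t_start_s, x_um, y_um,
    lifetime_frames``) appears as a 2-D Gaussian of the given amplitude for
    its lifetime.  Default noise SD is ``amplitude / snr``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if noise_sd is None:
        noise_sd = amplitude / snr
    n_px = int(round(field_um / pixel_size_um))
    movie = np.full((n_frames, n_px, n_px), background, dtype=float)
    yy, xx = np.mgrid[0:n_px, 0:n_px]
    s_px = sigma_um / pixel_size_um
    for _, row in condensates.iterrows():
        f0 = int(np.floor(row.t_start_s / frame_interval_s))
        f1 = min(f0 + int(row.lifetime_frames), n_frames)
        if f1 <= max(f0, 0):
            continue
        cx = row.x_um / pixel_size_um
        cy = row.y_um / pixel_size_um
        blob = amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * s_px ** 2))
        movie[max(f0, 0):f1] += blob
    movie += rng.normal(0.0, noise_sd, movie.shape)
    return movie
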