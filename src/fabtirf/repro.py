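"""End-to-end reproduction driver.

Each function here runs one headline analysis on freshly simulated data
with known ground truth and returns the recovered quantity: diffusion
coefficients from step-size fitting, the single-step bleaching fraction,
dwell-time recovery with photobleach correction, the fraction-bound
estimator, EC50 and potency-ratio recovery, the LAT event-ratio median,
and the tether-geometry spacings.  ``run_all`` assembles the full report.
"""

from __future__ import annotations

import numpy as np

from . import bleaching, condensates, detection, diffusion, geometry, kinetics
from .activation import fit_dose_response, potency_ratio
from .config import OpticsModel, SimConfig
from .render import render_movie
from .synthetic import (simulate_activation_population, simulate_dwell_events,
                        simulate_event_streams, simulate_intensity_traces,
                        simulate_trajectories)


def diffusion_recovery(d_true: float, seed: int,
                       n_molecules: int = 100,
                       n_frames: int = 551,
                       frame_interval: float = 0.02,
                       delays: tuple[float, ...] = (0.02, 0.04, 0.06)) -> dict:
    """Recover D by the multi-delay step-size fit on simulated tracks.

    Defaults give 55,000 one-frame steps at a 20 ms frame interval.
    """
    # large box: reflections shorten apparent steps, and a real bilayer is
    # unbounded at the scale of a trajectory
    cfg = SimConfig(box_size=500.0, d_free=d_true, d_bound=0.0, n_frames=n_frames,
                    rng_seed=seed)
    truth = simulate_trajectories(cfg, substeps_per_frame=1,
                                  frame_interval=frame_interval,
                                  n_molecules=n_molecules,
                                  rng=np.random.default_rng(seed))
    tracks = detection.tracks_from_truth(truth)
    data = diffusion.build_step_distributions(tracks, list(delays),
                                              frame_interval=frame_interval)
    fit = diffusion.fit_brownian(data)
    return {"D_um2_s": fit.D, "ci95": fit.ci95, "n_steps": data.n_steps,
            "n_independent": data.n_independent, "d_true": d_true}


def bleach_step_classification(seed: int, n_traces: int = 150,
                               snr: float = 5.0) -> dict:
    """Classify simulated single-fluorophore traces; report % single-step."""
    traces = simulate_intensity_traces(
        n_traces=n_traces, n_fluorophores=1, tau_bleach=3.0,
        frame_interval=0.1, n_frames=120, snr=snr,
        rng=np.random.default_rng(seed))
    res = bleaching.classify_population(traces)
    return {"percent_single_step": 100.0 * res.fractions["1"],
            "fractions": res.fractions, "n_traces": res.n_traces}


def coincidence(density: float = 0.06, radius: float = 0.2) -> dict:
    """Analytic below-diffraction-limit coincidence probability, %."""
    p = bleaching.coincidence_probability(density, radius)
    return {"percent": 100.0 * p, "density_per_um2": density, "radius_um": radius}


def dwell_recovery(seed: int, tau_off_true: float = 50.0,
                   n_events: int = 1000, lapse: float = 10.0,
                   tau_bleach: float = 300.0, exposure: float = 0.5) -> dict:
    """Photobleach-corrected dwell-time recovery at a 10 s frame lapse."""
    df = simulate_dwell_events(n_events, tau_off_true, tau_bleach, lapse,
                               exposure_s=exposure,
                               rng=np.random.default_rng(seed))
    recs = [kinetics.DwellRecord(duration=d, censored=bool(c))
            for d, c in zip(df.duration_s, df.censored)]
    fit = kinetics.fit_dwell_distribution(recs, lapse, tau_bleach,
                                          exposure=exposure)
    return {"tau_off_s": fit.tau_off, "tau_obs_s": fit.tau_obs,
            "ci95": fit.ci95, "n_events": fit.n_events,
            "tau_true_s": tau_off_true}


def dwell_lower_bound(seed: int, tau_off_true: float = 240.0,
                      n_events: int = 500, lapse: float = 10.0,
                      tau_bleach: float = 300.0, exposure: float = 0.5,
                      censor_time: float = 120.0, censor_sd: float = 10.0) -> dict:
    """Censored long-dwell fit: tracking loss near the cell center caps
    observation at ~2 min, so the corrected dwell time is a lower bound."""
    df = simulate_dwell_events(n_events, tau_off_true, tau_bleach, lapse,
                               exposure_s=exposure, censor_time_s=censor_time,
                               censor_sd_s=censor_sd,
                               rng=np.random.default_rng(seed))
    recs = [kinetics.DwellRecord(duration=d, censored=bool(c))
            for d, c in zip(df.duration_s, df.censored)]
    fit = kinetics.fit_dwell_distribution(recs, lapse, tau_bleach,
                                          exposure=exposure)
    return {"tau_off_lower_bound_min": fit.tau_off / 60.0,
            "tau_off_s": fit.tau_off, "lower_bound_flag": fit.lower_bound,
            "n_censored": fit.n_censored, "n_events": fit.n_events}


def fraction_bound_recovery(seed: int, true_fraction: float,
                            n_cells: int = 30,
                            footprint_um: float = 10.0,
                            density: float = 0.05,
                            n_pairs: int = 6) -> dict:
    """Median long/short-exposure fraction-bound estimate over cells.

    Each simulated cell has a 100 μm² footprint at the given ligand
    density; bound ligands diffuse at 0.01 and free at 2.5 μm²/s.  Per
    cell, ``n_pairs`` paired 500 ms / 20 ms frames are rendered and spot
    counts pooled before taking the ratio.
    """
    rng = np.random.default_rng(seed)
    long_optics = OpticsModel(exposure=0.5, frame_interval=0.5)
    short_optics = OpticsModel(exposure=0.02, frame_interval=0.5)
    mask = np.ones((int(footprint_um / long_optics.pixel_size),) * 2, dtype=bool)
    foot = kinetics.CellFootprint(mask=mask, pixel_size_um=long_optics.pixel_size)
    # long-exposure threshold calibrated to the sharp bound-spot response so
    # motion-blur streaks of free ligands are rejected; short-exposure
    # threshold is the robust noise-based auto threshold (all ligands)
    thr_long = 0.3 * detection.expected_spot_response(
        long_optics.photon_rate * long_optics.exposure, long_optics.psf_sigma,
        0.4, long_optics.pixel_size)
    estimates = []
    for c in range(n_cells):
        cfg = SimConfig(box_size=footprint_um, density=density, d_free=2.5,
                        d_bound=0.01, n_frames=n_pairs,
                        initial_bound_fraction=true_fraction,
                        rng_seed=seed + c)
        truth = simulate_trajectories(cfg, substeps_per_frame=250,
                                      frame_interval=0.5, rng=rng)
        if truth.n_molecules == 0:
            continue
        long_movie = render_movie(truth, long_optics, rng=rng)
        short_movie = render_movie(truth, short_optics, rng=rng)
        res = kinetics.estimate_fraction_bound(long_movie, short_movie, foot,
                                               threshold_long=thr_long)
        if res.valid:
            estimates.append(res.fraction)
    return {"median_fraction_bound": float(np.median(estimates)),
            "per_cell": estimates, "n_cells": len(estimates),
            "true_fraction": true_fraction}


def ec50_recovery(seed: int, ec50_true: float = 0.3, hill: float = 2.0,
                  max_resp: float = 0.9, n_cells: int = 200,
                  densities: tuple[float, ...] | None = None) -> dict:
    """Hill-fit EC50 recovery from a synthetic activation population."""
    if densities is None:
        densities = tuple(ec50_true * f for f in (1 / 6, 1 / 3, 1.0, 10 / 3, 10.0))
    cells = simulate_activation_population(list(densities), ec50_true, hill,
                                           max_resp, n_cells,
                                           np.random.default_rng(seed))
    fit = fit_dose_response(cells)
    return {"ec50": fit.ec50, "ec50_ci95": fit.ec50_ci95, "hill": fit.hill,
            "max_resp": fit.max_resp, "fit": fit, "ec50_true": ec50_true}


def potency_ratio_recovery(seed: int, ec50_a: float = 0.3,
                           ec50_b: float = 30.0, **kw) -> dict:
    """Recover the fold potency difference between two tether lengths."""
    fit_a = ec50_recovery(seed, ec50_true=ec50_a, **kw)
    fit_b = ec50_recovery(seed + 1, ec50_true=ec50_b, **kw)
    ratio, ci = potency_ratio(fit_a["fit"], fit_b["fit"])
    return {"ratio": ratio, "ci95": ci, "ec50_a": fit_a["ec50"],
            "ec50_b": fit_b["ec50"], "true_ratio": ec50_b / ec50_a}


def lat_ratio_recovery(seed: int, p_condensate: float = 0.6,
                       n_cells: int = 30, events_mean: float = 10.0,
                       background_rate: float = 0.0) -> dict:
    """Median per-cell condensate/binding-event ratio from event streams."""
    cells = simulate_event_streams(n_cells, events_mean, p_condensate,
                                   background_rate,
                                   np.random.default_rng(seed))
    ratios = condensates.compute_event_ratios(cells)
    summary = condensates.ratio_summary(ratios)
    return {"median_ratio": summary["median"], "iqr": summary["iqr"],
            "n_cells": summary["n_cells"], "p_true": p_condensate}


def tether_spacings() -> dict:
    """Calibrated maximum intermembrane spacings for the three designs."""
    designs = {"short_16nt": geometry.TetherDesign(16, 0, name="short"),
               "medium_36nt": geometry.TetherDesign(16, 19, name="medium"),
               "long_76nt": geometry.TetherDesign(16, 59, name="long")}
    return {k: geometry.max_spacing(d) for k, d in designs.items()}


def make_figures(seed: int, outdir) -> list[str]:
    """Write SVG summary figures for the main analyses; returns paths."""
    from pathlib import Path
    from . import plots
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    cfg = SimConfig(box_size=500.0, d_free=2.49, d_bound=0.0, n_frames=201,
                    rng_seed=seed)
    truth = simulate_trajectories(cfg, substeps_per_frame=1, frame_interval=0.02,
                                  n_molecules=60, rng=np.random.default_rng(seed))
    data = diffusion.build_step_distributions(detection.tracks_from_truth(truth),
                                              [0.02, 0.04, 0.06],
                                              frame_interval=0.02)
    p = outdir / "step_size_fit.svg"
    plots.plot_step_size_fit(data, diffusion.fit_brownian(data), p)
    written.append(str(p))

    fits = {}
    for off, (label, ec50) in enumerate((("short tether", 0.3),
                                         ("long tether", 30.0))):
        cells = simulate_activation_population(
            [ec50 * f for f in (1 / 6, 1 / 3, 1.0, 10 / 3, 10.0)],
            ec50, 2.0, 0.9, 200, np.random.default_rng(seed + off))
        fits[label] = fit_dose_response(cells)
    p = outdir / "dose_response.svg"
    plots.plot_dose_response(fits, p)
    written.append(str(p))

    groups = {}
    for label, prob in (("short", 0.6), ("long", 0.1)):
        cells = simulate_event_streams(30, 10.0, prob, 0.0,
                                       np.random.default_rng(seed + int(prob * 10)))
        ratios = condensates.compute_event_ratios(cells)
        groups[label] = [r.ratio for r in ratios if np.isfinite(r.ratio)]
    p = outdir / "event_ratios.svg"
    plots.plot_event_ratios(groups, p)
    written.append(str(p))

    per_cell = {}
    for label, frac in (("Fab'-DNA", 0.9), ("pMHC", 0.30)):
        per_cell[label] = fraction_bound_recovery(seed, frac,
                                                  n_cells=10)["per_cell"]
    p = outdir / "fraction_bound.svg"
    plots.plot_fraction_bound(per_cell, p)
    written.append(str(p))
    return written


def run_all(seed: int) -> dict:
    """Run every reproduction stage; returns a nested report dict."""
    report = {
        "diffusion_2c11": diffusion_recovery(2.49, seed),
        "diffusion_17a2": diffusion_recovery(2.83, seed + 1),
        "bleach_steps": bleach_step_classification(seed + 2),
        "coincidence": coincidence(),
        "dwell_pmhc": dwell_recovery(seed + 3),
        "dwell_lower_bound": dwell_lower_bound(seed + 4),
        "fraction_bound_high": fraction_bound_recovery(seed + 5, 0.9),
        "fraction_bound_pmhc": fraction_bound_recovery(seed + 6, 0.30),
        "ec50": {k: v for k, v in ec50_recovery(seed + 7).items() if k != "fit"},
        "potency_100x": {k: v for k, v in
                         potency_ratio_recovery(seed + 8).items()},
        "potency_10x": {k: v for k, v in
                        potency_ratio_recovery(seed + 9, ec50_b=3.0).items()},
        "lat_ratio": lat_ratio_recovery(seed + 10),
        "tether_spacing_nm": tether_spacings(),
    }
    return report
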