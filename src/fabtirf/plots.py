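"""Figure generation (SVG) for the pipeline reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .diffusion import DiffusionFit, StepSizeData, brownian_step_pdf


def plot_step_size_fit(data: StepSizeData, fit: DiffusionFit,
                       path: str | Path) -> None:
    """Step-size histograms at each delay with the fitted Brownian model."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for tau in data.delays:
        r = data.steps[tau]
        ax.hist(r, bins=50, density=True, alpha=0.35, label=f"τ = {tau:g} s")
        grid = np.linspace(0, r.max(), 200)
        ax.plot(grid, brownian_step_pdf(grid, tau, fit.D), "k-", lw=1)
    ax.set_xlabel("step size r (μm)")
    ax.set_ylabel("density")
    ax.set_title(f"D = {fit.D:.2f} μm²/s "
                 f"({fit.ci95[0]:.2f}–{fit.ci95[1]:.2f})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_dose_response(fits: dict, path: str | Path) -> None:
    """Fraction activated vs ligand density with fitted Hill curves."""
    from .activation import hill_curve
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, fit in fits.items():
        ax.errorbar(fit.densities, fit.fraction_activated, yerr=fit.se,
                    fmt="o", capsize=2, label=f"{label} (EC50 {fit.ec50:.2g})")
        grid = np.geomspace(fit.densities.min() / 3, fit.densities.max() * 3, 200)
        ax.plot(grid, hill_curve(grid, fit.ec50, fit.hill, fit.max_resp), lw=1)
    ax.set_xscale("log")
    ax.set_xlabel("ligand density (μm⁻²)")
    ax.set_ylabel("fraction of cells activated")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_event_ratios(groups: dict, path: str | Path) -> None:
    """Box plot of per-cell condensate/binding-event ratios per group."""
    fig, ax = plt.subplots(figsize=(4, 3.5))
    labels = list(groups)
    ax.boxplot([groups[k] for k in labels], tick_labels=labels, whis=1.5)
    ax.set_ylabel("LAT condensates per binding event")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_fraction_bound(per_cell: dict, path: str | Path) -> None:
    """Box plot of per-cell fraction-bound estimates per condition."""
    fig, ax = plt.subplots(figsize=(4, 3.5))
    labels = list(per_cell)
    ax.boxplot([per_cell[k] for k in labels], tick_labels=labels, whis=1.5)
    ax.set_ylabel("fraction of ligands bound")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
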