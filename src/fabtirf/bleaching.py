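"""Photobleaching step counting and the diffraction-limit coincidence bound.

A fluorophore bleaches in a single irreversible step, so the number of
downward intensity steps in a particle's trace counts the fluorophores it
carries.  Steps are found by penalized binary segmentation of the trace
into piecewise-constant segments; the multi-step fraction of a population
is compared against the probability that two independently placed
molecules sit closer than the diffraction limit.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.stats import binomtest


def _best_split(y: np.ndarray) -> tuple[int, float]:
    """Best single change point of a piecewise-constant mean model.

    Returns (index, SSE reduction); the split is between i-1 and i.
    Computed in O(n) with cumulative sums.
    """
    n = len(y)
    c = np.cumsum(y)
    tot = c[-1]
    i = np.arange(1, n)
    left_mean = c[:-1] / i
    right_mean = (tot - c[:-1]) / (n - i)
    # SSE reduction of splitting = between-group sum of squares
    gain = i * (n - i) / n * (left_mean - right_mean) ** 2
    k = int(np.argmax(gain))
    return k + 1, float(gain[k])


def _binary_segmentation(y: np.ndarray, penalty: float,
                         min_size: int = 2) -> list[int]:
    """Recursive binary segmentation; keeps splits whose SSE gain > penalty."""
    change_points: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < 2 * min_size:
            return
        seg = y[lo:hi]
        k, gain = _best_split(seg)
        if gain <= penalty or k < min_size or (hi - lo - k) < min_size:
            return
        change_points.append(lo + k)
        recurse(lo, lo + k)
        recurse(lo + k, hi)

    recurse(0, len(y))
    return sorted(change_points)


def estimate_noise_sd(intensity: np.ndarray) -> float:
    """Robust noise SD from the MAD of first differences (step-blind)."""
    d = np.diff(intensity)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / math.sqrt(2.0))


def count_bleach_steps(intensity: np.ndarray,
                       penalty: float | None = None,
                       min_step_sd: float = 3.0) -> tuple[int, list[int]]:
    """Count downward photobleaching steps in one intensity trace.

    The trace is segmented into piecewise-constant pieces by binary
    segmentation with a BIC-style penalty (default ``10 σ² log n`` with σ
    the robust noise SD); only downward mean shifts of at least
    ``min_step_sd`` noise SDs count as bleach steps.

    Returns ``(n_steps, change_point_frames)``.
    """
    y = np.asarray(intensity, dtype=float)
    if len(y) < 4:
        raise ValueError("trace shorter than 4 frames")
    sigma = estimate_noise_sd(y)
    if penalty is None:
        penalty = 10.0 * max(sigma, 1e-12) ** 2 * math.log(len(y))
    cps = _binary_segmentation(y, penalty)
    edges = [0] + cps + [len(y)]
    means = [y[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
    min_step = min_step_sd * sigma
    down = [cp for cp, a, b in zip(cps, means[:-1], means[1:])
            if (a - b) >= min_step]
    return len(down), down


@dataclasses.dataclass
class StepFractions:
    n_traces: int
    fractions: dict[str, float]            # "1", "2", ">=3", "0"
    ci95: dict[str, tuple[float, float]]   # binomial (Wilson) CIs


def classify_population(traces: pd.DataFrame,
                        penalty: float | None = None,
                        min_step_sd: float = 3.0) -> StepFractions:
    """Step-count fractions over a trace population.

    ``traces`` is long format with columns ``trace_id, t_s, intensity``.
    Fractions of 0-, 1-, 2- and ≥3-step traces are reported with Wilson
    binomial 95% CIs.
    """
    if traces.empty:
        raise ValueError("no traces supplied")
    counts = []
    for _, g in traces.groupby("trace_id", sort=True):
        n, _ = count_bleach_steps(g.sort_values("t_s").intensity.to_numpy(),
                                  penalty=penalty, min_step_sd=min_step_sd)
        counts.append(n)
    counts = np.asarray(counts)
    n = len(counts)
    if n < 50:
        import warnings
        warnings.warn(f"only {n} traces; >=50 recommended", stacklevel=2)
    cats = {"0": int((counts == 0).sum()), "1": int((counts == 1).sum()),
            "2": int((counts == 2).sum()), ">=3": int((counts >= 3).sum())}
    fr, ci = {}, {}
    for k, c in cats.items():
        fr[k] = c / n
        res = binomtest(c, n).proportion_ci(confidence_level=0.95, method="wilson")
        ci[k] = (float(res.low), float(res.high))
    return StepFractions(n_traces=n, fractions=fr, ci95=ci)


def coincidence_probability(density: float, radius: float) -> float:
    """P(≥1 neighbour within ``radius``) under Poisson placement.

    For molecules scattered as a spatial Poisson process at surface density
    ρ (μm⁻²), the probability that a given molecule has at least one
    neighbour within r (μm) — i.e. appears as an unresolvable multi-emitter
    spot below the diffraction limit — is ``1 − exp(−ρ π r²)``.
    """
    if density < 0 or radius < 0:
        raise ValueError("density and radius must be >= 0")
    return float(-np.expm1(-density * math.pi * radius ** 2))
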