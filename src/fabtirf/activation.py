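"""NFAT translocation scoring and dose-response (EC50) fitting.

A cell is activated when its calcium pathway drives the NFAT reporter from
the cytosol into the nucleus, i.e. the background-subtracted
nucleus/cytosol intensity ratio exceeds one.  The fraction of activated
cells versus ligand surface density is fitted with a Hill curve

    f(ρ) = max_resp · ρ^h / (ρ^h + EC50^h)

by binomial maximum likelihood; EC50 confidence intervals come from the
profile likelihood.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize
from skimage.filters import gaussian, threshold_otsu


@dataclasses.dataclass
class CellRecord:
    cell_id: int
    ligand_density: float     # molecules/μm²
    nfat_ratio: float
    activated: bool
    footprint_area_um2: float = math.nan
    qc_flags: tuple[str, ...] = ()


@dataclasses.dataclass
class DoseResponse:
    densities: np.ndarray
    fraction_activated: np.ndarray
    se: np.ndarray
    n_cells: np.ndarray
    ec50: float
    ec50_ci95: tuple[float, float]
    hill: float
    max_resp: float
    converged: bool = True
    flags: tuple[str, ...] = ()


def hill_curve(rho: np.ndarray, ec50: float, hill: float, max_resp: float) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    return max_resp * rho ** hill / (rho ** hill + ec50 ** hill)


def score_nfat(nfat_image: np.ndarray,
               nucleus_mask: np.ndarray,
               cytosol_mask: np.ndarray,
               background: float) -> tuple[float, bool, tuple[str, ...]]:
    """Background-subtracted nucleus/cytosol ratio; activated if ratio > 1.

    Cells whose cytosolic mean does not exceed background cannot be scored
    (no reporter signal) and are flagged for exclusion.
    """
    if not nucleus_mask.any() or not cytosol_mask.any():
        raise ValueError("empty nucleus or cytosol mask")
    if (nucleus_mask & cytosol_mask).any():
        raise ValueError("nucleus and cytosol masks overlap")
    img = np.asarray(nfat_image, dtype=float)
    nuc = img[nucleus_mask].mean() - background
    cyt = img[cytosol_mask].mean() - background
    if cyt <= 0:
        return math.nan, False, ("cytosol_at_background",)
    ratio = nuc / cyt
    return float(ratio), bool(ratio > 1.0), ()


@dataclasses.dataclass
class SegmentationResult:
    nucleus_mask: np.ndarray | None
    cytosol_mask: np.ndarray | None
    qc_flags: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.qc_flags


def segment_nucleus_cytosol(nfat_image: np.ndarray,
                            footprint: np.ndarray,
                            guard_px: int = 2,
                            smooth_sigma_px: float = 2.0,
                            min_nucleus_px: int = 25) -> SegmentationResult:
    """Split a cell footprint into nucleus and cytosol masks.

    The nucleus is the largest smooth interior region whose intensity
    contrasts with the cytosol (brighter in activated cells, darker in
    resting cells): the smoothed in-footprint intensities are split by
    Otsu's threshold and the candidate region must not touch the footprint
    boundary ("clear nuclei" rule).  The cytosol is the footprint minus the
    nucleus with a guard band of ``guard_px`` pixels.
    """
    footprint = footprint.astype(bool)
    img = gaussian(np.asarray(nfat_image, dtype=float), smooth_sigma_px,
                   preserve_range=True)
    vals = img[footprint]
    if vals.size == 0:
        return SegmentationResult(None, None, ("empty_footprint",))
    if vals.std() < 1e-9 or np.ptp(vals) < 1e-9:
        return SegmentationResult(None, None, ("no_intensity_structure",))
    thr = threshold_otsu(vals)
    if vals.std() < 0.02 * abs(vals.mean()):
        return SegmentationResult(None, None, ("no_intensity_structure",))
    boundary = footprint & ~ndimage.binary_erosion(footprint, iterations=2)

    def interior_candidate(mask: np.ndarray) -> np.ndarray | None:
        mask = mask & footprint
        lab, n = ndimage.label(mask)
        best, best_size = None, 0
        for i in range(1, n + 1):
            comp = lab == i
            size = int(comp.sum())
            if size < min_nucleus_px or (comp & boundary).any():
                continue
            if size > best_size:
                best, best_size = comp, size
        return best

    cands = [c for c in (interior_candidate(img > thr),
                         interior_candidate(img < thr)) if c is not None]
    if not cands:
        return SegmentationResult(None, None, ("no_clear_nucleus",))
    # if both intensity classes have an interior component, the nucleus is
    # the more compact (rounder) one
    def compactness(m: np.ndarray) -> float:
        filled = ndimage.binary_fill_holes(m)
        per = filled & ~ndimage.binary_erosion(filled)
        return float(filled.sum()) / max(float(per.sum()) ** 2, 1.0)

    nucleus = max(cands, key=compactness)
    nucleus = ndimage.binary_fill_holes(nucleus)
    guard = ndimage.binary_dilation(nucleus, iterations=guard_px)
    cytosol = footprint & ~guard
    if not cytosol.any():
        return SegmentationResult(None, None, ("no_cytosol",))
    return SegmentationResult(nucleus, cytosol, ())


def _fit_binomial_hill(rho: np.ndarray, k: np.ndarray, n: np.ndarray,
                       hill_bounds: tuple[float, float],
                       fixed_max_resp: float | None):
    """Binomial ML Hill fit; returns (ec50, hill, max_resp, nll, ok)."""
    eps = 1e-9

    def unpack(theta):
        ec50 = math.exp(theta[0])
        h = theta[1]
        m = fixed_max_resp if fixed_max_resp is not None else 1.0 / (1.0 + math.exp(-theta[2]))
        return ec50, h, m

    def nll(theta):
        ec50, h, m = unpack(theta)
        p = np.clip(hill_curve(rho, ec50, h, m), eps, 1 - eps)
        return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())

    frac = k.sum() / n.sum()
    x0 = [math.log(np.median(rho)), 1.0]
    bounds = [(math.log(rho.min()) - 7, math.log(rho.max()) + 7), hill_bounds]
    if fixed_max_resp is None:
        m0 = min(max(k / np.maximum(n, 1)) if len(k) else frac, 0.97)
        x0.append(math.log(max(m0, 0.05) / (1 - max(m0, 0.05))))
        bounds.append((-6, 6))
    best = None
    for h0 in (0.8, 1.5, 3.0):
        x = list(x0)
        x[1] = h0
        res = minimize(nll, x, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    ec50, h, m = unpack(best.x)
    return ec50, h, m, float(best.fun), bool(best.success)


def fit_dose_response(cells: list[CellRecord] | pd.DataFrame,
                      hill_bounds: tuple[float, float] = (0.5, 4.0),
                      fixed_max_resp: float | None = None) -> DoseResponse:
    """Fit a Hill dose-response to per-cell activation outcomes.

    ``cells`` is a list of :class:`CellRecord` or a frame with columns
    ``density`` (or ``ligand_density``) and ``activated``.  The Hill
    coefficient is bounded (default [0.5, 4]) for stability; fixing
    ``fixed_max_resp`` reproduces the extrapolated-fit convention used
    when a weak ligand never reaches its plateau.  The EC50 CI is from
    the profile likelihood (χ²₁ cutoff).
    """
    if isinstance(cells, pd.DataFrame):
        df = cells.rename(columns={"ligand_density": "density"})
    else:
        df = pd.DataFrame({"density": [c.ligand_density for c in cells],
                           "activated": [c.activated for c in cells]})
    grp = df.groupby("density")["activated"].agg(["sum", "count"]).reset_index()
    rho = grp.density.to_numpy(dtype=float)
    k = grp["sum"].to_numpy(dtype=float)
    n = grp["count"].to_numpy(dtype=float)
    if len(rho) < 3:
        raise ValueError("need >=3 distinct densities")
    if np.any(rho <= 0):
        raise ValueError("densities must be > 0")
    frac = k / n
    se = np.sqrt(frac * (1 - frac) / n)
    flags = []
    if np.any(n < 50):
        flags.append("fewer_than_50_cells_per_condition")
    if k.sum() == 0:
        return DoseResponse(rho, frac, se, n, ec50=float(rho.max()),
                            ec50_ci95=(float(rho.max()), math.inf),
                            hill=math.nan, max_resp=0.0, converged=False,
                            flags=("all_zero_activation", "ec50_lower_bound"))

    ec50, h, m, nll0, ok = _fit_binomial_hill(rho, k, n, hill_bounds, fixed_max_resp)

    # profile likelihood on log(ec50)
    def profile_nll(log_e):
        eps = 1e-9

        def nll(theta):
            hh = theta[0]
            mm = fixed_max_resp if fixed_max_resp is not None else 1.0 / (1.0 + math.exp(-theta[1]))
            p = np.clip(hill_curve(rho, math.exp(log_e), hh, mm), eps, 1 - eps)
            return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())

        x0 = [h] + ([] if fixed_max_resp is not None else
                    [math.log(max(m, 1e-3) / max(1 - m, 1e-3))])
        bnds = [hill_bounds] + ([] if fixed_max_resp is not None else [(-6.0, 6.0)])
        return minimize(nll, x0, method="L-BFGS-B", bounds=bnds).fun

    cut = nll0 + 1.92  # chi2_1(0.95)/2
    lo = hi = math.log(ec50)
    step = 0.05
    for _ in range(400):
        if profile_nll(lo - step) > cut:
            break
        lo -= step
    for _ in range(400):
        if profile_nll(hi + step) > cut:
            break
        hi += step
    ci = (math.exp(lo - step), math.exp(hi + step))
    return DoseResponse(rho, frac, se, n, ec50=ec50, ec50_ci95=ci, hill=h,
                        max_resp=m, converged=ok, flags=tuple(flags))


def potency_ratio(fit_a: DoseResponse, fit_b: DoseResponse) -> tuple[float, tuple[float, float]]:
    """EC50 ratio b/a with a log-scale error-propagated 95% CI.

    A ratio > 1 means ligand *b* is less potent (needs a higher density).
    If either EC50 is only a lower bound the CI is one-sided.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    ratio = fit_b.ec50 / fit_a.ec50

    def log_se(fit: DoseResponse) -> float:
        lo, hi = fit.ec50_ci95
        if not np.isfinite(hi):
            return math.inf
        return math.log(hi / lo) / (2 * 1.96)

    s = math.hypot(log_se(fit_a), log_se(fit_b))
    if math.isinf(s):
        return ratio, (ratio * math.exp(-1.96 * log_se(fit_a)), math.inf)
    return ratio, (ratio * math.exp(-1.96 * s), ratio * math.exp(1.96 * s))
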