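"""NFAT scoring, nucleus segmentation, Hill dose-response fitting."""

import math

import numpy as np
import pandas as pd
import pytest

from fabtirf.activation import (fit_dose_response, hill_curve, potency_ratio,
                                score_nfat, segment_nucleus_cytosol)
from fabtirf.synthetic import simulate_activation_population, simulate_nfat_cell


class TestScoreNfat:
    def _masks(self):
        nuc = np.zeros((20, 20), bool)
        nuc[8:12, 8:12] = True
        cyt = np.zeros((20, 20), bool)
        cyt[2:6, 2:18] = True
        return nuc, cyt

    def test_uniform_cell_is_not_activated(self):
        nuc, cyt = self._masks()
        img = np.full((20, 20), 300.0)
        ratio, act, flags = score_nfat(img, nuc, cyt, background=100.0)
        assert ratio == pytest.approx(1.0)
        assert not act

    def test_two_to_one_cell_scores_two_and_activates(self, rng):
        img, foot, nuc = simulate_nfat_cell(nucleus_to_cytosol=2.0, rng=rng)
        seg = segment_nucleus_cytosol(img, foot)
        assert seg.ok
        ratio, act, _ = score_nfat(img, seg.nucleus_mask, seg.cytosol_mask, 100.0)
        assert ratio == pytest.approx(2.0, abs=0.05)
        assert act

    def test_cytosol_at_background_flagged(self):
        nuc, cyt = self._masks()
        img = np.full((20, 20), 100.0)
        img[nuc] = 300.0
        ratio, act, flags = score_nfat(img, nuc, cyt, background=100.0)
        assert "cytosol_at_background" in flags
        assert math.isnan(ratio) and not act

    def test_empty_mask_rejected(self):
        nuc, cyt = self._masks()
        with pytest.raises(ValueError):
            score_nfat(np.ones((20, 20)), np.zeros((20, 20), bool), cyt, 0.0)

    def test_affine_intensity_invariance(self, rng):
        nuc, cyt = self._masks()
        img = np.full((20, 20), 200.0)
        img[nuc] = 500.0
        r1, _, _ = score_nfat(img, nuc, cyt, background=100.0)
        r2, _, _ = score_nfat(3.0 * img + 40.0, nuc, cyt,
                              background=3.0 * 100.0 + 40.0)
        assert r2 == pytest.approx(r1, rel=1e-9)


class TestSegmentation:
    @pytest.mark.parametrize("contrast", [2.0, 0.4])
    def test_nucleus_recovered_for_bright_and_dark_nuclei(self, contrast):
        img, foot, nuc = simulate_nfat_cell(nucleus_to_cytosol=contrast,
                                            rng=np.random.default_rng(2))
        seg = segment_nucleus_cytosol(img, foot)
        assert seg.ok
        iou = (seg.nucleus_mask & nuc).sum() / (seg.nucleus_mask | nuc).sum()
        assert iou >= 0.8

    def test_structureless_footprint_excluded(self, rng):
        img = np.full((60, 60), 300.0) + rng.normal(0, 1.0, (60, 60))
        foot = np.zeros((60, 60), bool)
        foot[10:50, 10:50] = True
        seg = segment_nucleus_cytosol(img, foot)
        assert not seg.ok

    def test_nucleus_touching_footprint_edge_excluded(self):
        img, foot, nuc = simulate_nfat_cell(
            nucleus_offset_px=(0, 30), rng=np.random.default_rng(3))
        seg = segment_nucleus_cytosol(img, foot)
        assert not seg.ok


class TestDoseResponse:
    def test_exact_curve_points_recover_parameters(self):
        rho = [0.1, 0.2, 0.3, 0.6, 1.2, 3.0]
        rows = []
        for r in rho:
            p = float(hill_curve(np.array([r]), 0.3, 2.0, 0.8)[0])
            n = 1000
            k = round(p * n)
            rows.append(pd.DataFrame({"density": r,
                                      "activated": [True] * k + [False] * (n - k)}))
        fit = fit_dose_response(pd.concat(rows))
        assert fit.ec50 == pytest.approx(0.3, rel=1e-2)
        assert fit.hill == pytest.approx(2.0, rel=2e-2)
        assert fit.max_resp == pytest.approx(0.8, rel=1e-2)

    def test_synthetic_population_recovers_ec50_in_printed_band(self, rng):
        cells = simulate_activation_population([0.05, 0.1, 0.3, 1.0, 3.0],
                                               0.3, 2.0, 0.9, 200, rng)
        fit = fit_dose_response(cells)
        assert 0.2 <= fit.ec50 <= 0.4
        assert fit.ec50_ci95[0] < fit.ec50 < fit.ec50_ci95[1]

    def test_all_zero_activation_flagged(self):
        df = pd.DataFrame({"density": [0.1] * 60 + [0.3] * 60 + [1.0] * 60,
                           "activated": False})
        fit = fit_dose_response(df)
        assert not fit.converged
        assert "all_zero_activation" in fit.flags

    def test_too_few_densities_rejected(self, rng):
        cells = simulate_activation_population([0.1, 1.0], 0.3, 2.0, 0.9, 50, rng)
        with pytest.raises(ValueError):
            fit_dose_response(cells)

    def test_density_unit_rescaling_scales_ec50(self, rng):
        cells = simulate_activation_population([0.05, 0.1, 0.3, 1.0, 3.0],
                                               0.3, 2.0, 0.9, 150, rng)
        fit = fit_dose_response(cells)
        scaled = cells.assign(density=cells.density * 1000.0)
        fit_scaled = fit_dose_response(scaled)
        assert fit_scaled.ec50 == pytest.approx(1000.0 * fit.ec50, rel=1e-3)

    def test_ec50_recovery_and_ci_coverage_over_replicates(self):
        """Median recovered EC50 within 15% of truth; CI coverage ≥ 90%."""
        ec50s, covered = [], 0
        n_rep = 40
        for s in range(n_rep):
            rng = np.random.default_rng(20_000 + s)
            cells = simulate_activation_population([0.05, 0.1, 0.3, 1.0, 3.0],
                                                   0.3, 2.0, 0.9, 200, rng)
            fit = fit_dose_response(cells)
            ec50s.append(fit.ec50)
            covered += fit.ec50_ci95[0] <= 0.3 <= fit.ec50_ci95[1]
        assert abs(np.median(ec50s) - 0.3) / 0.3 < 0.15
        assert covered / n_rep >= 0.90


class TestPotencyRatio:
    def _fake_fit(self, ec50):
        from fabtirf.activation import DoseResponse
        return DoseResponse(np.array([1.0]), np.array([0.5]), np.array([0.1]),
                            np.array([100]), ec50=ec50,
                            ec50_ci95=(0.8 * ec50, 1.25 * ec50), hill=2.0,
                            max_resp=0.9)

    def test_tenfold_and_hundredfold(self):
        assert potency_ratio(self._fake_fit(0.3), self._fake_fit(3.0))[0] \
            == pytest.approx(10.0)
        assert potency_ratio(self._fake_fit(0.3), self._fake_fit(30.0))[0] \
            == pytest.approx(100.0)

    def test_identical_fits_give_unit_ratio(self):
        f = self._fake_fit(0.3)
        ratio, ci = potency_ratio(f, f)
        assert ratio == pytest.approx(1.0)
        assert ci[0] < 1.0 < ci[1]
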