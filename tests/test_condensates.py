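"""Condensate detection/tracking, event ratios, group comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from fabtirf.condensates import (colocalize_events, compare_groups,
                                 compute_event_ratios,
                                 detect_and_track_condensates, ratio_summary,
                                 significance_stars)
from fabtirf.synthetic import render_condensate_movie, simulate_event_streams


def _one_condensate(lifetime, n_frames=15):
    cond = pd.DataFrame([{"t_start_s": 2.0, "x_um": 5.0, "y_um": 5.0,
                          "lifetime_frames": lifetime}])
    return render_condensate_movie(cond, n_frames=n_frames, noise_sd=1.0,
                                   rng=np.random.default_rng(0))


class TestDetection:
    def test_long_lived_condensate_yields_one_track(self):
        assert len(detect_and_track_condensates(_one_condensate(10))) == 1

    def test_three_frame_condensate_filtered_at_four_frame_persistence(self):
        assert detect_and_track_condensates(_one_condensate(3),
                                            min_lifetime=4) == []
        assert len(detect_and_track_condensates(_one_condensate(4),
                                                min_lifetime=4)) == 1

    def test_persistence_filter_monotone(self):
        movie = _one_condensate(6)
        counts = [len(detect_and_track_condensates(movie, min_lifetime=m))
                  for m in (1, 4, 8)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_known_grid_recall_and_precision_at_snr_4(self):
        rng = np.random.default_rng(6)
        rows = []
        for i, j in itertools.product(range(4), range(4)):
            rows.append({"t_start_s": float(rng.integers(0, 10)) * 2.0,
                         "x_um": 1.5 + 2.3 * i + rng.normal(0, 0.1),
                         "y_um": 1.5 + 2.3 * j + rng.normal(0, 0.1),
                         "lifetime_frames": 6})
        cond = pd.DataFrame(rows)
        movie = render_condensate_movie(cond, n_frames=20, snr=4.0, rng=rng)
        tracks = detect_and_track_condensates(movie)
        det = [(t.x.mean(), t.y.mean()) for t in tracks]
        matched_truth = sum(
            any(np.hypot(dx - r.x_um, dy - r.y_um) < 0.5 for dx, dy in det)
            for r in cond.itertuples())
        matched_det = sum(
            any(np.hypot(dx - r.x_um, dy - r.y_um) < 0.5
                for r in cond.itertuples())
            for dx, dy in det)
        assert matched_truth / len(cond) >= 0.9          # recall
        assert matched_det / max(len(det), 1) >= 0.9     # precision


class TestEventRatios:
    def test_zero_probability_gives_zero_ratios(self):
        cells = simulate_event_streams(10, 8.0, 0.0, 0.0, 3)
        ratios = compute_event_ratios(cells)
        vals = [r.ratio for r in ratios if not np.isnan(r.ratio)]
        assert all(v == 0.0 for v in vals)

    def test_certain_condensation_gives_unit_ratios(self):
        cells = simulate_event_streams(10, 8.0, 1.0, 0.0, 3, lag_max_s=0.0)
        ratios = compute_event_ratios(cells)
        vals = [r.ratio for r in ratios if not np.isnan(r.ratio)]
        assert all(v == 1.0 for v in vals)

    def test_zero_event_cells_kept_with_flag(self):
        cells = simulate_event_streams(5, 0.0, 0.6, 2.0, 3)
        ratios = compute_event_ratios(cells)
        assert all("no_binding_events" in r.flags for r in ratios)
        assert all(np.isnan(r.ratio) for r in ratios)

    def test_median_ratio_estimates_condensation_probability(self):
        cells = simulate_event_streams(30, 10.0, 0.6, 0.0, 1)
        med = ratio_summary(compute_event_ratios(cells))["median"]
        assert abs(med - 0.6) <= 0.15


class TestCompareGroups:
    def test_identical_samples_not_significant(self):
        a = np.linspace(0.1, 0.9, 10)
        u, p, stars = compare_groups(a, a.copy())
        assert p > 0.9
        assert stars == "ns"

    def test_separated_groups_highly_significant(self, rng):
        a = rng.normal(0.6, 0.15, 30)
        b = rng.normal(0.1, 0.08, 30)
        _, p, stars = compare_groups(a, b)
        assert p < 0.001
        assert stars in ("***", "****")

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], [1, 2, 3, 4, 5])

    def test_outlier_shifts_u_by_at_most_n(self, rng):
        a = rng.normal(0.5, 0.1, 12)
        b = a.copy()
        b[0] = 50.0
        u, _, _ = compare_groups(a, b)
        assert abs(u - 12 * 12 / 2) <= 12

    def test_u_distribution_matches_exact_enumeration(self):
        """Mann-Whitney p-value equals the brute-force permutation null for
        small samples without ties."""
        a = np.array([0.11, 0.52, 0.74, 0.93])
        b = np.array([0.25, 0.38, 0.67])
        u_obs = sum((x > y) for x in a for y in b)
        pooled = np.concatenate([a, b])
        n_a = len(a)
        us = []
        for idx in itertools.combinations(range(len(pooled)), n_a):
            ga = pooled[list(idx)]
            gb = np.delete(pooled, list(idx))
            us.append(sum((x > y) for x in ga for y in gb))
        us = np.array(us)
        dev = abs(u_obs - n_a * len(b) / 2)
        p_exact = np.mean(np.abs(us - n_a * len(b) / 2) >= dev)
        res = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(p_exact, abs=1e-12)

    def test_star_thresholds(self):
        assert significance_stars(5e-5) == "****"
        assert significance_stars(5e-4) == "***"
        assert significance_stars(0.5) == "ns"


class TestColocalization:
    def test_nearby_delayed_condensate_is_colocalized(self):
        ev = pd.DataFrame({"t_s": [10.0], "x_um": [5.0], "y_um": [5.0]})
        cond = pd.DataFrame({"t_start_s": [15.0], "x_um": [5.2], "y_um": [5.0]})
        assert colocalize_events(ev, cond).tolist() == [True]

    def test_distant_condensate_is_not_colocalized(self):
        ev = pd.DataFrame({"t_s": [10.0], "x_um": [5.0], "y_um": [5.0]})
        cond = pd.DataFrame({"t_start_s": [15.0], "x_um": [0.0], "y_um": [0.0]})
        assert colocalize_events(ev, cond).tolist() == [False]

    def test_condensate_before_event_is_not_colocalized(self):
        ev = pd.DataFrame({"t_s": [10.0], "x_um": [5.0], "y_um": [5.0]})
        cond = pd.DataFrame({"t_start_s": [8.0], "x_um": [5.0], "y_um": [5.0]})
        assert colocalize_events(ev, cond).tolist() == [False]

    def test_label_accuracy_on_ground_truth_pairing(self):
        cells = simulate_event_streams(10, 10.0, 0.7, 0.0, 11)
        accs = []
        for c in cells:
            if len(c.binding_events) == 0:
                continue
            labels = colocalize_events(c.binding_events, c.condensates)
            truth = np.zeros(len(c.binding_events), dtype=bool)
            truth[[int(s) for s in c.condensates.source_event if s >= 0]] = True
            accs.append((labels == truth).mean())
        assert np.mean(accs) >= 0.95
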