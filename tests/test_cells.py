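"""Morphology, motility, speed, and protrusion-dynamics analytics."""

import math

import numpy as np
import pandas as pd
import pytest

from matrixplast.cells import (CellMask, CellTrack, ProtrusionSeries,
                               circularity, classify_motile, fit_sinusoid,
                               max_speed, motility_probability,
                               protrusion_stats)
from matrixplast.synth import (TrackSimParams, generate_shape_mask,
                               generate_tracks)


def make_track(positions, dt_min=10.0, **kw):
    pos = np.asarray(positions, dtype=float)
    df = pd.DataFrame({"t_min": np.arange(len(pos)) * dt_min,
                       "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2]})
    return CellTrack(cell_id=kw.pop("cell_id", 0), samples=df, **kw)


class TestCircularity:
    def test_disk_scores_one(self):
        mask, _ = generate_shape_mask("disk", size_px=100)
        assert circularity(mask) == pytest.approx(1.0, rel=0.02)

    def test_square_scores_pi_over_four(self):
        mask, _ = generate_shape_mask("rectangle", size_px=100, aspect=1.0)
        assert circularity(mask) == pytest.approx(math.pi / 4, rel=0.02)

    def test_two_to_one_ellipse(self):
        mask, _ = generate_shape_mask("ellipse", size_px=100, aspect=2.0)
        assert circularity(mask) == pytest.approx(0.84, abs=0.02)

    def test_isoperimetric_bound_and_monotone_in_aspect(self):
        values = []
        for aspect in (1.0, 1.5, 2.0, 3.0):
            mask, _ = generate_shape_mask("ellipse", size_px=80, aspect=aspect)
            c = circularity(mask)
            assert c <= 1.02  # raster tolerance on the isoperimetric bound
            values.append(c)
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_empty_and_multicomponent_rejected(self):
        with pytest.raises(ValueError):
            circularity(CellMask(np.zeros((10, 10), dtype=bool)))
        two = np.zeros((20, 20), dtype=bool)
        two[2:5, 2:5] = True
        two[12:15, 12:15] = True
        with pytest.raises(ValueError, match="one component"):
            circularity(CellMask(two))


class TestMotilityClassification:
    def test_stationary_track(self):
        motile, net = classify_motile(make_track([[0, 0, 0]] * 5))
        assert not motile and net == 0.0

    def test_threshold_is_strict(self):
        """Displacement of exactly one cell radius (14 um) does not count;
        15 um does."""
        at_threshold = make_track([[0, 0, 0], [14.0, 0, 0]])
        beyond = make_track([[0, 0, 0], [15.0, 0, 0]])
        assert not classify_motile(at_threshold)[0]
        assert classify_motile(beyond)[0]

    def test_peak_displacement_counts_even_if_cell_returns(self):
        track = make_track([[0, 0, 0], [20.0, 0, 0], [1.0, 0, 0]])
        motile, net = classify_motile(track)
        assert motile and net == pytest.approx(20.0)

    def test_rigid_motion_invariance(self):
        pos = np.array([[0, 0, 0], [5, 3, 1], [20, 4, 2.]])
        base = classify_motile(make_track(pos))
        shifted = classify_motile(make_track(pos + [100.0, -50.0, 7.0]))
        th = np.deg2rad(63.0)
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        rotated = classify_motile(make_track(pos @ rot.T))
        assert base[0] == shifted[0] == rotated[0]
        assert base[1] == pytest.approx(shifted[1]) == pytest.approx(rotated[1])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            classify_motile(make_track([[0, 0, 0]]))


class TestMotilityProbability:
    def test_limit_proportions(self):
        still = [make_track([[0, 0, 0]] * 3, cell_id=i) for i in range(10)]
        p, (lo, hi) = motility_probability(still)
        assert p == 0.0 and lo == 0.0
        movers = [make_track([[0, 0, 0], [20.0, 0, 0]], cell_id=i)
                  for i in range(10)]
        p2, (_, hi2) = motility_probability(movers)
        assert p2 == 1.0 and hi2 == 1.0

    def test_excluded_tracks_are_dropped(self):
        ts = [make_track([[0, 0, 0], [20.0, 0, 0]], cell_id=0),
              make_track([[0, 0, 0], [0.1, 0, 0]], cell_id=1, excluded=True)]
        p, _ = motility_probability(ts)
        assert p == 1.0

    def test_wilson_interval_covers_generator_fraction(self):
        """Calibration: over seeded repeats, the 95% Wilson CI contains the
        generator's motile fraction in >= 93% of runs."""
        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            tracks = generate_tracks(TrackSimParams(
                n_cells=150, motile_fraction=0.4, duration=24.0, dt=20.0,
                seed=seed))
            _, (lo, hi) = motility_probability(tracks)
            hits += lo <= 0.4 <= hi
        assert hits / n_rep >= 0.93


class TestMaxSpeed:
    def test_stationary_and_constant_velocity(self):
        assert max_speed(make_track([[0, 0, 0]] * 4)) == 0.0
        # 10 um/h = 1.6667 um per 10 min step along x
        steps = np.arange(5)[:, None] * [10.0 / 6.0, 0, 0]
        assert max_speed(make_track(steps)) == pytest.approx(10.0)

    def test_generator_speed_recovered(self):
        params = TrackSimParams(n_cells=25, motile_fraction=1.0,
                                speed_range=(20.0, 20.0), duration=6.0,
                                seed=4)
        tracks = generate_tracks(params)
        speeds = [max_speed(t) for t in tracks]
        # per-step displacement shrinks slightly under angular diffusion
        assert np.median(speeds) == pytest.approx(20.0, rel=0.10)


class TestSinusoidFit:
    def test_exact_sinusoid_recovered(self):
        t = np.arange(0.0, 360.0, 5.0)
        y = 3.0 * np.sin(2 * np.pi * t / 90.0 + 0.5) + 8.0
        fit = fit_sinusoid(ProtrusionSeries(t, y))
        assert fit.amplitude == pytest.approx(3.0, rel=1e-6)
        assert fit.period == pytest.approx(90.0, rel=1e-6)
        assert fit.phase == pytest.approx(0.5, rel=1e-5)
        assert fit.offset == pytest.approx(8.0, rel=1e-6)
        assert fit.rmse < 1e-9

    def test_constant_series_zero_amplitude(self):
        t = np.arange(0.0, 100.0, 5.0)
        fit = fit_sinusoid(ProtrusionSeries(t, np.full_like(t, 6.0)))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-6)

    def test_noisy_series_period_within_five_percent(self):
        """6 h at 5-min sampling, 10% amplitude noise (invadopodia-like
        oscillation, period 1.5 h)."""
        rng = np.random.default_rng(12)
        t = np.arange(0.0, 360.0, 5.0)
        clean = 4.0 * np.sin(2 * np.pi * t / 90.0 + 1.0) + 10.0
        y = clean + rng.normal(0, 0.4, t.shape)
        fit = fit_sinusoid(ProtrusionSeries(t, y))
        assert fit.period == pytest.approx(90.0, rel=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_sinusoid(ProtrusionSeries(np.arange(5.0), np.arange(5.0)))


class TestProtrusionStats:
    def test_single_measurement_lands_in_one_bin(self):
        out = protrusion_stats(pd.DataFrame({"length_um": [12.3]}))
        assert out["length_counts"].sum() == 1
        idx = np.searchsorted(out["length_bin_edges"], 12.3) - 1
        assert out["length_counts"][idx] == 1

    def test_degenerate_equal_lengths(self):
        out = protrusion_stats(pd.DataFrame({"length_um": [5.0] * 9}))
        assert (out["length_counts"] > 0).sum() == 1
        assert out["length_median"] == 5.0

    def test_generated_lengths_match_distribution(self):
        """Histogram of generator-drawn lengths is consistent with the
        sampled distribution (chi-square goodness of fit)."""
        from scipy import stats
        rng = np.random.default_rng(7)
        lengths = rng.uniform(5.0, 25.0, 400)
        edges = np.linspace(5.0, 25.0, 9)
        out = protrusion_stats(pd.DataFrame({"length_um": lengths,
                                             "width_um": lengths / 5}),
                               length_bins=edges)
        expected = np.full(8, len(lengths) / 8)
        _, pval = stats.chisquare(out["length_counts"], expected)
        assert pval > 0.01
        assert out["width_median"] == pytest.approx(np.median(lengths / 5))


class TestGeneratorClassifierAgreement:
    def test_accuracy_on_12h_tracks(self):
        """Ground-truth labels recovered at >= 95% over 12 h tracks."""
        tracks = generate_tracks(TrackSimParams(n_cells=200,
                                                motile_fraction=0.5,
                                                duration=12.0, seed=21))
        correct = sum(classify_motile(t)[0] == (t.condition == "motile")
                      for t in tracks)
        assert correct / len(tracks) >= 0.95
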