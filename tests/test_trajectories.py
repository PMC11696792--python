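"""Single-cell migration statistics: speed, autocorrelation, persistence fit."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cellmig import synthetic as syn
from cellmig import trajectories as tj


def _track(points, cell_id="c1"):
    pts = np.asarray(points, dtype=float)
    return tj.Track(cell_id=cell_id, t_min=pts[:, 0], x_um=pts[:, 1], y_um=pts[:, 2])


# ---------------------------------------------------------------- I/O

class TestReadTracks:
    def test_groups_and_sorts_by_cell(self):
        csv = io.StringIO(
            "cell_id,frame,t_min,x_um,y_um\n"
            "a,0,0,0,0\na,1,10,1,0\na,2,20,2,0\n"
            "b,0,0,5,5\nb,1,10,6,5\nb,2,20,7,5\n"
        )
        tracks = tj.read_tracks(csv)
        assert [t.cell_id for t in tracks] == ["a", "b"]
        assert all(t.n_points == 3 for t in tracks)

    def test_empty_file_with_header(self):
        assert tj.read_tracks(io.StringIO("cell_id,frame,t_min,x_um,y_um\n")) == []

    def test_duplicated_cell_frame_rejected(self):
        csv = io.StringIO(
            "cell_id,frame,t_min,x_um,y_um\na,0,0,0,0\na,0,0,1,0\na,1,10,2,0\n"
        )
        with pytest.raises(ValueError, match="duplicated"):
            tj.read_tracks(csv)

    def test_non_uniform_dt_names_cell(self):
        csv = io.StringIO(
            "cell_id,frame,t_min,x_um,y_um\nbad,0,0,0,0\nbad,1,10,1,0\nbad,2,35,2,0\n"
        )
        with pytest.raises(ValueError, match="bad"):
            tj.read_tracks(csv)

    def test_malformed_rows_reported_with_line_numbers(self):
        csv = io.StringIO(
            "cell_id,frame,t_min,x_um,y_um\na,0,0,0,0\na,1,10,,0\n"
        )
        with pytest.raises(ValueError, match="line"):
            tj.read_tracks(csv)

    def test_roundtrip(self, tmp_path, small_cohort):
        tracks, _ = small_cohort
        path = tmp_path / "tracks.csv"
        tj.write_tracks(tracks, path)
        back = tj.read_tracks(path)
        assert len(back) == len(tracks)
        np.testing.assert_allclose(back[0].x_um, tracks[0].x_um)


# ---------------------------------------------------------------- speed

@pytest.mark.parametrize(
    "points, expected",
    [
        ([(0, 0, 0), (10, 10, 0)], 1.0),                        # 10 µm in 10 min
        ([(0, 3, 4), (10, 3, 4), (20, 3, 4)], 0.0),              # stationary
        ([(0, 0, 0), (10, 3, 0), (20, 7, 0), (30, 12, 0)], 0.4),  # (3+4+5)/3/10
    ],
)
def test_cell_speed(points, expected):
    assert tj.cell_speed(_track(points)) == pytest.approx(expected)


# ---------------------------------------------------------------- autocorrelation

class TestDirectionAutocorrelation:
    def test_straight_line_is_one_at_every_lag(self):
        pts = [(10 * i, 2.0 * i, -1.0 * i) for i in range(10)]
        c = tj.direction_autocorrelation(_track(pts), 4)
        np.testing.assert_allclose(c.values, 1.0, atol=1e-12)

    def test_alternating_east_north_steps(self):
        # steps E, N, E, N: perpendicular at lag 1, parallel at lag 2
        pts = [(0, 0, 0), (10, 1, 0), (20, 1, 1), (30, 2, 1), (40, 2, 2)]
        c = tj.direction_autocorrelation(_track(pts), 2)
        assert c.values[0] == 1.0
        assert c.values[1] == pytest.approx(0.0, abs=1e-12)
        assert c.values[2] == pytest.approx(1.0)

    def test_single_reversal(self):
        pts = [(0, 0, 0), (10, 1, 0), (20, 0, 0)]
        c = tj.direction_autocorrelation(_track(pts), 1)
        assert c.values[1] == pytest.approx(-1.0)

    def test_lag0_is_one_and_npairs_non_increasing(self, small_cohort):
        tracks, _ = small_cohort
        c = tj.direction_autocorrelation(tracks[0], 19)
        assert c.values[0] == 1.0
        assert np.all(np.diff(c.n_pairs) <= 0)
        assert np.all((c.values >= -1) & (c.values <= 1))

    def test_zero_length_steps_dropped_not_zero_angle(self):
        # middle step has zero length; pairs containing it are dropped
        pts = [(0, 0, 0), (10, 1, 0), (20, 1, 0), (30, 2, 0)]
        c = tj.direction_autocorrelation(_track(pts), 1)
        assert c.n_pairs[1] == 0  # both lag-1 pairs touch the zero step
        assert np.isnan(c.values[1])

    def test_degenerate_track_rejected(self):
        pts = [(0, 0, 0), (10, 0, 0), (20, 0, 0), (30, 0, 0)]
        with pytest.raises(ValueError, match="degenerate"):
            tj.direction_autocorrelation(_track(pts), 1)

    @settings(deadline=None, max_examples=20)
    @given(angle=st.floats(0, 2 * np.pi), dx=st.floats(-50, 50), dy=st.floats(-50, 50))
    def test_invariant_under_rotation_and_translation(self, angle, dx, dy):
        rng = np.random.default_rng(7)
        xy = np.cumsum(rng.normal(0, 3, size=(12, 2)), axis=0)
        t = np.arange(12) * 10.0
        base = tj.Track("c", t, xy[:, 0], xy[:, 1])
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        xy2 = xy @ rot.T + [dx, dy]
        moved = tj.Track("c", t, xy2[:, 0], xy2[:, 1])
        c1 = tj.direction_autocorrelation(base, 5)
        c2 = tj.direction_autocorrelation(moved, 5)
        np.testing.assert_allclose(c1.values, c2.values, atol=1e-9)


# ---------------------------------------------------------------- persistence fit

def _model_curve(a, b, lags):
    return tj.AutocorrCurve(lags, (1 - b) * np.exp(-lags / a) + b, np.ones_like(lags))


class TestFitPersistence:
    def test_noiseless_exact_recovery(self):
        lags = np.arange(0, 130, 10.0)
        fit = tj.fit_persistence(_model_curve(50.0, 0.4, lags))
        assert fit.converged
        assert fit.a_min == pytest.approx(50.0, rel=1e-6)
        assert fit.b == pytest.approx(0.4, rel=1e-6)
        assert fit.predict(np.array([0.0]))[0] == pytest.approx(1.0)

    def test_plateau_only_limit(self):
        lags = np.arange(0, 60, 10.0)
        fit = tj.fit_persistence(tj.AutocorrCurve(lags, np.ones_like(lags), np.ones_like(lags)))
        assert fit.b == 1.0
        assert np.isinf(fit.a_min)
        assert fit.converged

    def test_needs_four_lags_with_zero(self):
        with pytest.raises(ValueError):
            tj.fit_persistence(_model_curve(50, 0, np.array([0.0, 10.0, 20.0])))

    def test_matches_grid_search_oracle_on_noiseless_curves(self):
        """Dense (a, b) grid search agrees with the nonlinear fitter."""
        rng = np.random.default_rng(42)
        lags = np.arange(0, 200, 10.0)
        for _ in range(10):
            a_true = rng.uniform(20, 150)
            b_true = rng.uniform(-0.3, 0.8)
            curve = _model_curve(a_true, b_true, lags)
            fit = tj.fit_persistence(curve)
            # brute force around truth, 0.1% steps in a, 0.001 in b
            a_grid = a_true * np.arange(0.9, 1.1, 0.001)
            b_grid = np.arange(b_true - 0.05, b_true + 0.05, 0.001)
            E = np.exp(-lags[None, :] / a_grid[:, None])
            best = (np.inf, None, None)
            for b in b_grid:
                rss = (((1 - b) * E + b) - curve.values) ** 2
                tot = rss.sum(axis=1)
                i = int(np.argmin(tot))
                if tot[i] < best[0]:
                    best = (tot[i], a_grid[i], b)
            assert fit.rss <= best[0] + 1e-12
            assert fit.a_min == pytest.approx(best[1], rel=2e-3)
            assert fit.b == pytest.approx(best[2], abs=2e-3)

    def test_simulated_cohort_recovers_tau(self, small_cohort):
        """Median per-cell decay constant within 15% of the planted tau."""
        tracks, truth = small_cohort
        fits = tj.fit_cohort(tracks)
        assert fits["a_min"].median() == pytest.approx(truth["tau_min"], rel=0.15)


# ---------------------------------------------------------------- comparison

class TestComparePersistence:
    def _fits(self, bias, seed):
        tracks, _ = syn.gen_tracks(
            syn.TrackSimConfig(n_cells=60, duration_min=390, tau_min=60,
                               bias=bias, seed=seed)
        )
        return tj.fit_cohort(tracks)

    def test_identical_groups_give_null_result(self):
        fits = self._fits(0.0, 5)
        res = tj.compare_persistence(fits, fits, n_boot=2000, seed=0)
        assert res.effect == 0.0
        assert res.p_value > 0.8

    def test_label_swap_flips_effect_keeps_p(self):
        fa, fb = self._fits(0.0, 5), self._fits(0.5, 6)
        r1 = tj.compare_persistence(fa, fb, n_boot=2000, seed=0)
        r2 = tj.compare_persistence(fb, fa, n_boot=2000, seed=0)
        assert r1.effect == pytest.approx(-r2.effect)
        assert r1.p_value == pytest.approx(r2.p_value, abs=0.02)

    def test_detects_planted_plateau_difference(self):
        """Bias 0 vs 0.5 cohorts (n=60) separate at alpha=0.05."""
        for rep in range(5):
            fa = self._fits(0.0, 100 + rep)
            fb = self._fits(0.5, 200 + rep)
            res = tj.compare_persistence(fa, fb, n_boot=2000, seed=rep)
            assert res.p_value < 0.05
            assert res.effect < 0  # biased group has the higher plateau

    def test_small_group_rejected(self):
        fits = self._fits(0.0, 5)
        with pytest.raises(ValueError, match="group"):
            tj.compare_persistence(fits.iloc[:1], fits)
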