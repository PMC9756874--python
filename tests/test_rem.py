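"""REM estimator, independence filter and survey design."""

import math
import warnings
from datetime import datetime, timedelta

import numpy as np
import pytest

from rewildscape import rem
from rewildscape import synthetic_data as sd
from rewildscape.raster import Raster

from conftest import make_bundle, make_deployments


def brute_force_independent(records, window_minutes=10.0):
    """Sequential-scan oracle for the last-kept independence rule."""
    kept = []
    streams = {}
    for r in sorted(records, key=lambda r: (r.camera_id, r.species, r.timestamp)):
        key = (r.camera_id, r.species)
        stream = streams.setdefault(key, [])
        if not stream or (r.timestamp - stream[-1]).total_seconds() >= window_minutes * 60:
            stream.append(r.timestamp)
            kept.append(r)
    return kept


def _recs(minutes, camera="C1", species="roe_deer"):
    t0 = datetime(2021, 6, 1)
    return [
        rem.DetectionRecord(camera, species, t0 + timedelta(minutes=m)) for m in minutes
    ]


class TestFilterIndependent:
    def test_keeps_first_and_post_window(self):
        out = rem.filter_independent(_recs([0, 5, 12]))
        assert [r.timestamp.minute for r in out] == [0, 12]

    def test_exactly_ten_minutes_is_independent(self):
        assert len(rem.filter_independent(_recs([0, 10]))) == 2

    def test_single_record_kept(self):
        recs = _recs([3])
        assert rem.filter_independent(recs) == recs

    def test_simultaneous_on_different_cameras_both_kept(self):
        recs = _recs([0]) + _recs([0], camera="C2")
        assert len(rem.filter_independent(recs)) == 2

    def test_empty_input(self):
        assert rem.filter_independent([]) == []

    def test_matches_oracle_and_idempotent_on_random_streams(self):
        rng = np.random.default_rng(42)
        t0 = datetime(2021, 6, 1)
        for _ in range(300):
            n = int(rng.integers(0, 30))
            recs = [
                rem.DetectionRecord(
                    f"C{int(rng.integers(3))}",
                    ["roe_deer", "red_deer"][int(rng.integers(2))],
                    t0 + timedelta(minutes=float(rng.uniform(0, 120))),
                )
                for _ in range(n)
            ]
            out = rem.filter_independent(recs)
            assert out == brute_force_independent(recs)
            assert rem.filter_independent(out) == out
            assert len(out) <= len(recs)


class TestAverageDetectionParams:
    def test_mixed_radii(self):
        specs = [rem.CameraSpec("a", r, 1.0) for r in (20, 20, 12, 20)]
        r, _ = rem.average_detection_params(specs)
        assert r == pytest.approx(18.0)

    def test_theta_mean(self):
        specs = [rem.CameraSpec("a", 20, 0.87), rem.CameraSpec("b", 20, 2.09)]
        _, theta = rem.average_detection_params(specs)
        assert theta == pytest.approx(1.48)

    def test_single_spec_identity(self):
        r, theta = rem.average_detection_params([rem.CameraSpec("a", 12, 1.75)])
        assert (r, theta) == (12.0, 1.75)

    def test_empty_rejected(self):
        with pytest.raises(rem.NoDataError):
            rem.average_detection_params([])


class TestRemDensity:
    def test_zero_events_zero_density(self):
        assert rem.rem_density(0, 100, 1.99, 20, 0.87) == 0.0

    def test_linear_in_y_inverse_in_v(self):
        base = rem.rem_density(10, 100, 1.99, 20, 0.87)
        assert rem.rem_density(20, 100, 1.99, 20, 0.87) == pytest.approx(2 * base)
        assert rem.rem_density(10, 100, 3.98, 20, 0.87) == pytest.approx(base / 2)

    def test_closed_form(self):
        # (y/t) * pi / (v * r_km * (2+theta))
        d = rem.rem_density(36.4, 100, 1.99, 20, 0.87)
        assert d == pytest.approx((36.4 / 100) * math.pi / (1.99 * 0.02 * 2.87))

    def test_monotone_decreasing_in_geometry(self):
        d = rem.rem_density(10, 100, 1.99, 20, 0.87)
        assert rem.rem_density(10, 100, 1.99, 25, 0.87) < d
        assert rem.rem_density(10, 100, 1.99, 20, 1.5) < d

    def test_invalid_effort(self):
        with pytest.raises(rem.InvalidEffortError):
            rem.rem_density(10, 0, 1.99, 20, 0.87)

    def test_forward_inverse_consistency(self, uniform_field):
        """Estimator applied to the forward model recovers the truth.

        Four cameras at 700 trap-days give ~1018 expected events; a single
        survey estimate should land within a few percent of D = 10.
        """
        deps = make_deployments(n_cameras=4, trap_days=700.0)
        records = sd.simulate_detections(uniform_field, deps, 1.99, seed=1)
        records = rem.filter_independent(records)
        y = len(records)
        t = sum(d.trap_days for d in deps)
        d_hat = rem.rem_density(y, t, 1.99, 20, 0.87)
        assert d_hat == pytest.approx(10.0, rel=0.15)


class TestEstimateCell:
    def test_zero_events(self, four_cameras):
        est = rem.estimate_cell([], four_cameras, rem.SpeciesParams("roe_deer", 1.99))
        assert (est.density, est.se, est.n_events) == (0.0, 0.0, 0)
        assert est.trap_days == pytest.approx(400.0)

    def test_single_camera_degenerate_se(self):
        deps = make_deployments(n_cameras=1)
        recs = _recs([0, 30, 60], camera=deps[0].camera_id)
        with pytest.warns(UserWarning, match="degenerate"):
            est = rem.estimate_cell(recs, deps, rem.SpeciesParams("roe_deer", 1.99))
        assert est.se == 0.0
        assert est.n_events == 3

    def test_no_deployments_rejected(self):
        with pytest.raises(rem.NoDataError):
            rem.estimate_cell([], [], rem.SpeciesParams("roe_deer", 1.99))

    def test_bootstrap_se_tracks_replicate_sd(self, uniform_field):
        """Mean bootstrap SE within 50% of the SD over 200 replicate surveys."""
        params = rem.SpeciesParams("roe_deer", 1.99)
        deps = make_deployments(n_cameras=4, trap_days=50.0)
        estimates, ses = [], []
        for s in range(200):
            records = rem.filter_independent(
                sd.simulate_detections(uniform_field, deps, 1.99, seed=1000 + s)
            )
            est = rem.estimate_cell(records, deps, params, bootstrap_B=200, seed=s)
            estimates.append(est.density)
            ses.append(est.se)
        empirical_sd = np.std(estimates, ddof=1)
        mean_boot_se = np.mean(ses)
        assert abs(mean_boot_se - empirical_sd) < 0.5 * empirical_sd


class TestSurveyDesign:
    def _mask(self, value=1.0):
        return Raster(np.full((200, 200), value), xmin=0, ymax=20_000, resolution=100)

    def test_quadrat_count_from_geometry(self):
        cells = rem.build_survey_design((0, 0, 20_000, 20_000), self._mask(), 4, seed=0)
        assert len(cells) == 4
        assert len({c.quadrat_id for c in cells}) == 4

    def test_unsuitable_quadrat_never_selected(self):
        mask = self._mask()
        mask.data[:100, :100] = 0.0  # NW quadrat fully unsuitable
        for seed in range(10):
            cells = rem.build_survey_design((0, 0, 20_000, 20_000), mask, 3, seed=seed)
            assert all(c.quadrat_id != "Q10" for c in cells)  # row 1, col 0 = NW

    def test_deterministic(self):
        a = rem.build_survey_design((0, 0, 20_000, 20_000), self._mask(), 4, seed=5)
        b = rem.build_survey_design((0, 0, 20_000, 20_000), self._mask(), 4, seed=5)
        assert [c.cell_bounds for c in a] == [c.cell_bounds for c in b]

    def test_corners_inset_within_cell(self):
        cells = rem.build_survey_design((0, 0, 20_000, 20_000), self._mask(), 4, seed=1)
        for c in cells:
            x0, y0, x1, y1 = c.cell_bounds
            assert len(c.corner_points) == 4
            for x, y in c.corner_points:
                assert x0 < x < x1 and y0 < y < y1

    def test_insufficient_support(self):
        empty = self._mask(0.0)
        with pytest.raises(rem.InsufficientSupportError):
            rem.build_survey_design((0, 0, 20_000, 20_000), empty, 1, seed=0)
        with pytest.raises(rem.InsufficientSupportError):
            rem.build_survey_design((0, 0, 9_000, 9_000), self._mask(), 1, seed=0)


def test_csv_round_trip(tmp_path, four_cameras):
    recs = _recs([0, 15, 30], camera=four_cameras[0].camera_id)
    det_path = tmp_path / "det.csv"
    dep_path = tmp_path / "dep.csv"
    rem.write_detections_csv(recs, det_path)
    rem.write_deployments_csv(four_cameras, dep_path)
    assert rem.read_detections_csv(det_path) == recs
    back = rem.read_deployments_csv(dep_path)
    assert [d.camera_id for d in back] == [d.camera_id for d in four_cameras]
    assert back[0].spec == four_cameras[0].spec
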