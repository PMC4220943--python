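"""Locating error, reorientation error, DX, A3r, ICC and summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from cephorient import (
    DegenerateAngleError,
    InsufficientDataError,
    LandmarkSet,
    TrialPair,
    a3r,
    dx_metric,
    icc_per_coordinate,
    locating_error,
    reorientation_error,
    summarize_records,
)
from cephorient.metrics import (
    ErrorRecord,
    averaged_reoriented_landmark,
    pair_records,
)
from conftest import AXIS_ALIGNED_REFS, random_reference_trial


def _pair_from(points_a, points_b):
    return TrialPair.from_trials(
        LandmarkSet("p1", "T1", points_a), LandmarkSet("p1", "T2", points_b))


def _noisy_copy(trial, rng, sd, trial_id="T2", only=None):
    pts = {}
    for name, p in trial.points.items():
        noise = rng.normal(0, sd, 3) if (only is None or name in only) else 0.0
        pts[name] = p + noise
    return LandmarkSet(trial.patient_id, trial_id, pts)


class TestLocatingError:
    def test_identical_placements(self, axis_aligned_trial):
        pair = _pair_from(axis_aligned_trial.points, axis_aligned_trial.points)
        assert locating_error(pair, "Na") == (0, 0, 0, 0)

    def test_three_four_five(self):
        pair = _pair_from({"Q": (0, 0, 0)}, {"Q": (0.3, 0.4, 0.0)})
        dx, dy, dz, db = locating_error(pair, "Q")
        assert (dx, dy, dz) == pytest.approx((0.3, 0.4, 0.0))
        assert db == pytest.approx(0.5)

    def test_db_is_root_sum_of_squares(self, rng):
        for _ in range(20):
            a, b = rng.uniform(-5, 5, 3), rng.uniform(-5, 5, 3)
            dx, dy, dz, db = locating_error(_pair_from({"Q": a}, {"Q": b}), "Q")
            assert db == pytest.approx(math.sqrt(dx**2 + dy**2 + dz**2),
                                       abs=1e-12)


class TestReorientationError:
    def test_mlws_is_exactly_zero(self, rng):
        a = random_reference_trial(rng)
        b = _noisy_copy(a, rng, 0.5)
        assert reorientation_error(TrialPair.from_trials(a, b), "MLWS") == 0.0

    def test_identical_frames_reduce_to_locating_error(self, rng):
        """With identical reference landmarks the two reorientations are
        the same rigid map, so Y equals Db."""
        a = random_reference_trial(rng)
        b = _noisy_copy(a, rng, 0.5, only={"Me"})
        pair = TrialPair.from_trials(a, b)
        y = reorientation_error(pair, "Me")
        db = locating_error(pair, "Me")[3]
        assert y == pytest.approx(db, abs=1e-9)

    def test_reference_jitter_creates_error_without_locating_error(self, rng):
        """Perturbed reference landmarks with an identical target give
        Y > 0 while Db = 0; the value matches an independent dual-frame
        computation using scipy rotations."""
        a = random_reference_trial(rng)
        b = _noisy_copy(a, rng, 0.5, only={"Na", "S", "Ba", "MLWS"})
        pair = TrialPair.from_trials(a, b)
        assert locating_error(pair, "Me")[3] == 0.0
        y = reorientation_error(pair, "Me")
        assert y > 0.0

        # dual-path oracle: align the canonical basis onto each frame's
        # axes with scipy, then compare the mapped target offsets
        from cephorient import build_reference_frame
        mats = []
        for t in (a, b):
            f = build_reference_frame(t)
            rot, rssd = Rotation.align_vectors(
                np.eye(3), [f.x_axis, f.y_axis, f.z_axis])
            assert rssd < 1e-9
            mats.append((rot.as_matrix(), f.origin))
        ra = mats[0][0] @ (a["Me"] - mats[0][1])
        rb = mats[1][0] @ (b["Me"] - mats[1][1])
        assert y == pytest.approx(np.linalg.norm(ra - rb), abs=1e-9)

    def test_symmetric_in_trial_order(self, rng):
        a = random_reference_trial(rng)
        b = _noisy_copy(a, rng, 0.4)
        fwd = TrialPair.from_trials(a, b)
        rev = TrialPair.from_trials(b, a)
        for metric in (reorientation_error, dx_metric, a3r):
            assert metric(fwd, "Me") == pytest.approx(metric(rev, "Me"),
                                                      abs=1e-9)
        assert locating_error(fwd, "Me")[3] == pytest.approx(
            locating_error(rev, "Me")[3], abs=1e-12)

    def test_invariant_under_global_rigid_motion(self, rng):
        a = random_reference_trial(rng)
        b = _noisy_copy(a, rng, 0.4)
        pair = TrialPair.from_trials(a, b)
        rot = Rotation.random(random_state=11).as_matrix()
        t = rng.uniform(-40, 40, 3)
        moved = TrialPair.from_trials(a.transformed(rot, t),
                                      b.transformed(rot, t))
        for metric in (reorientation_error, dx_metric, a3r):
            assert metric(moved, "Me") == pytest.approx(metric(pair, "Me"),
                                                        abs=1e-9)
        assert locating_error(moved, "Me")[3] == pytest.approx(
            locating_error(pair, "Me")[3], abs=1e-9)

    def test_mean_y_monotone_in_reference_noise(self, rng):
        """Statistically, more reference-landmark noise cannot reduce the
        mean reorientation error of a fixed-noise target."""
        base = LandmarkSet("p1", "T1", {
            **{k: np.asarray(v, float) for k, v in AXIS_ALIGNED_REFS.items()},
            "Me": np.array([0.0, 45.0, -115.0]),
        })
        means = []
        for ref_sd in (0.1, 0.3, 0.6):
            ys = []
            for _ in range(200):
                a = _noisy_copy(base, rng, ref_sd, "T1",
                                only={"MLWS", "Na", "S", "Ba"})
                a = _noisy_copy(a, rng, 0.3, "T1", only={"Me"})
                b = _noisy_copy(base, rng, ref_sd, "T2",
                                only={"MLWS", "Na", "S", "Ba"})
                b = _noisy_copy(b, rng, 0.3, "T2", only={"Me"})
                ys.append(reorientation_error(TrialPair.from_trials(a, b), "Me"))
            means.append(np.mean(ys))
        assert means[0] <= means[1] <= means[2]


class TestA3r:
    def test_identical_references_give_zero(self, rng):
        a = random_reference_trial(rng)
        b = _noisy_copy(a, rng, 0.5, only={"Me"})
        # clamped arccos near 1 resolves zero angles only to ~1e-6 degrees
        assert a3r(TrialPair.from_trials(a, b), "Me") == pytest.approx(
            0.0, abs=1e-5)

    def test_right_angle_configuration(self):
        pts_a = {"Na": (0, 50, 0), "Ba": (0, -30, -20),
                 "S": (1.0, 0, 0), "Q": (1, 1, 1)}
        pts_b = {"Na": (0, 50, 0), "Ba": (0, -30, -20),
                 "S": (0, 1.0, 0), "Q": (-1, -1, -1)}
        # averaged Q is the origin; S moves through 90 degrees seen from it
        pair = _pair_from(pts_a, pts_b)
        assert a3r(pair, "Q") == pytest.approx(90.0, abs=1e-9)

    def test_matches_atan2_oracle(self, rng):
        for _ in range(30):
            a = random_reference_trial(rng)
            b = _noisy_copy(a, rng, 1.0)
            pair = TrialPair.from_trials(a, b)
            a_bar = 0.5 * (a["Me"] + b["Me"])
            expected = 0.0
            for ref in ("Na", "S", "Ba"):
                u, v = a[ref] - a_bar, b[ref] - a_bar
                expected += math.degrees(math.atan2(
                    np.linalg.norm(np.cross(u, v)), float(u @ v)))
            assert a3r(pair, "Me") == pytest.approx(expected, abs=1e-9)

    def test_reference_at_averaged_landmark_is_degenerate(self):
        pts = {"Na": (0.0, 0, 0), "S": (0, 50, 0), "Ba": (0, -30, -20),
               "Q": (0, 0, 0)}
        with pytest.raises(DegenerateAngleError):
            a3r(_pair_from(pts, pts), "Q")


class TestDXMetric:
    def test_mlws_with_identical_references_is_zero(self, rng):
        a = random_reference_trial(rng)
        b = _noisy_copy(a, rng, 0.5, only={"Me"})
        assert dx_metric(TrialPair.from_trials(a, b), "MLWS") == pytest.approx(
            0.0, abs=1e-12)

    def test_axis_aligned_value(self):
        pts = dict(AXIS_ALIGNED_REFS)
        pts["Q"] = np.array([0.0, 2.0, 0.0]) + np.array([7.0, 3.0, 4.0])
        pair = _pair_from(pts, pts)
        assert dx_metric(pair, "Q") == pytest.approx(5.0, abs=1e-9)

    def test_matches_point_line_distance_oracle(self, rng):
        """DX equals the 3D point-to-line distance from the averaged
        landmark to the averaged x axis through the averaged origin."""
        from cephorient import build_reference_frame
        for _ in range(20):
            a = random_reference_trial(rng)
            b = _noisy_copy(a, rng, 0.5)
            pair = TrialPair.from_trials(a, b)
            avg_refs = {n: 0.5 * (a[n] + b[n])
                        for n in ("MLWS", "Na", "S", "Ba")}
            f = build_reference_frame(LandmarkSet("p1", "avg", avg_refs))
            a_bar = 0.5 * (a["Me"] + b["Me"])
            d = np.linalg.norm(np.cross(a_bar - f.origin, f.x_axis))
            assert dx_metric(pair, "Me") == pytest.approx(d, abs=1e-9)


class TestPairRecords:
    def test_db_identity_and_a3r_policy(self, rng):
        a = random_reference_trial(rng)
        b = _noisy_copy(a, rng, 0.4)
        recs = {r.landmark: r for r in pair_records(TrialPair.from_trials(a, b))}
        for r in recs.values():
            assert r.db_mm**2 == pytest.approx(
                r.dxerr_mm**2 + r.dyerr_mm**2 + r.dzerr_mm**2, abs=1e-9)
            assert r.db_mm >= 0 and r.y_mm >= 0 and r.dx_axis_mm >= 0
        assert math.isnan(recs["Na"].a3r_deg)
        assert 0.0 <= recs["Me"].a3r_deg <= 540.0

    def test_axis_distance_properties_from_avg_coords(self, rng):
        a = random_reference_trial(rng)
        b = _noisy_copy(a, rng, 0.4)
        pair = TrialPair.from_trials(a, b)
        rec = {r.landmark: r for r in pair_records(pair)}["Me"]
        c = averaged_reoriented_landmark(pair, "Me")
        assert rec.dy_axis_mm == pytest.approx(math.hypot(c[0], c[2]), abs=1e-9)
        assert rec.dz_axis_mm == pytest.approx(math.hypot(c[0], c[1]), abs=1e-9)
        assert rec.d0_mm == pytest.approx(np.linalg.norm(c), abs=1e-9)


def _icc3_oracle(values):
    """ICC(3,1) from the two-way ANOVA mean squares (patients x trials)."""
    v = np.asarray(values, float)      # shape (n_subjects, k_raters)
    n, k = v.shape
    grand = v.mean()
    ms_r = k * np.sum((v.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((v.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = np.sum((v - v.mean(axis=1, keepdims=True)
                  - v.mean(axis=0, keepdims=True) + grand) ** 2)
    ms_e = sse / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)


class TestICC:
    @staticmethod
    def _trials_from_matrix(values):
        trials = []
        for i in range(values.shape[0]):
            for j in range(values.shape[1]):
                trials.append(LandmarkSet(
                    f"p{i:03d}", f"T{j + 1}",
                    {"Me": np.array([values[i, j], 0.0, 0.0])}))
        return trials

    def test_identical_trials_give_one(self):
        vals = np.tile(np.arange(5, dtype=float).reshape(-1, 1) * 10, (1, 3))
        table = icc_per_coordinate(self._trials_from_matrix(vals))
        assert table.loc[(table.axis == "x"), "icc"].iloc[0] == pytest.approx(1.0)

    def test_pure_noise_is_near_zero(self, rng):
        vals = rng.normal(size=(200, 3))
        table = icc_per_coordinate(self._trials_from_matrix(vals))
        assert abs(table.loc[(table.axis == "x"), "icc"].iloc[0]) < 0.2

    def test_large_between_patient_variance_gives_high_icc(self, rng):
        vals = rng.normal(0, 10, size=(20, 1)) + rng.normal(0, 0.3, size=(20, 3))
        table = icc_per_coordinate(self._trials_from_matrix(vals))
        assert table.loc[(table.axis == "x"), "icc"].iloc[0] > 0.99

    def test_matches_anova_oracle(self, rng):
        vals = rng.normal(0, 3, size=(12, 1)) + rng.normal(0, 1.0, size=(12, 3))
        table = icc_per_coordinate(self._trials_from_matrix(vals))
        assert table.loc[(table.axis == "x"), "icc"].iloc[0] == pytest.approx(
            _icc3_oracle(vals), abs=1e-9)

    def test_insufficient_data(self):
        trials = self._trials_from_matrix(np.zeros((1, 3)))
        with pytest.raises(InsufficientDataError):
            icc_per_coordinate(trials)


class TestSummaries:
    @staticmethod
    def _record(landmark, y, patient="p1", pair="T1-T2"):
        return ErrorRecord(patient, pair, landmark, db_mm=y, dxerr_mm=y,
                           dyerr_mm=0, dzerr_mm=0, y_mm=y, dx_axis_mm=y,
                           a3r_deg=y, avg_reoriented=np.zeros(3))

    def test_inclusive_quartiles(self):
        recs = [self._record("Me", v) for v in (1.0, 2.0, 3.0, 4.0)]
        row = summarize_records(recs).iloc[0]
        assert row.Y_mean == pytest.approx(2.5)
        assert row.Y_q1 == pytest.approx(1.75)
        assert row.Y_q3 == pytest.approx(3.25)
        assert row.Y_sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))

    def test_single_record_has_undefined_sd(self):
        row = summarize_records([self._record("Me", 2.0)]).iloc[0]
        assert row.Y_mean == pytest.approx(2.0)
        assert math.isnan(row.Y_sd)

    def test_mlws_row_is_zero_for_any_cohort(self, default_cohort):
        from cephorient import compute_error_records
        recs = compute_error_records(default_cohort.trials)
        row = summarize_records(recs).set_index("landmark").loc["MLWS"]
        assert row.Y_mean == 0.0 and row.Y_sd == 0.0
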