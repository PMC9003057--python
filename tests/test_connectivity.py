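"""Pooled R2 scoring, pairwise matrices, baseline correction, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gsconn.connectivity import (
    ConnectivityMatrix,
    baseline_correct,
    frame_to_matrices,
    matrices_to_frame,
    pairwise_matrix,
    r2_score,
    read_matrices_csv,
    read_matrices_json,
    write_matrices_csv,
    write_matrices_json,
)
from gsconn.model import TrainConfig
from gsconn.preprocess import THETA, TimeWindow
from gsconn.regions import RegionDefinition, RegionTrajectory


def brute_force_r2(actual, predicted):
    """Independent double-loop evaluation of the pooled R2 ratio."""
    d_dim, n = actual.shape
    num = 0.0
    den = 0.0
    for d in range(d_dim):
        ybar = sum(actual[d, i] for i in range(n)) / n
        for i in range(n):
            num += (actual[d, i] - predicted[d, i]) ** 2
            den += (actual[d, i] - ybar) ** 2
    return 1.0 - num / den


class TestR2Score:
    def test_perfect_prediction_scores_one(self, rng):
        y = rng.standard_normal((3, 50))
        assert r2_score(y, y.copy()).value == 1.0

    def test_mean_prediction_scores_zero(self, rng):
        y = rng.standard_normal((3, 50))
        pred = np.repeat(y.mean(axis=1, keepdims=True), 50, axis=1)
        assert r2_score(y, pred).value == 0.0

    def test_hand_built_case_matches_oracle(self):
        actual = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [0.0, 0.0, 1.0]])
        predicted = np.array([[1.1, 1.9, 3.2], [2.5, 3.5, 6.0], [0.0, 0.5, 0.5]])
        got = r2_score(actual, predicted).value
        assert got == pytest.approx(brute_force_r2(actual, predicted), abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_oracle_on_random_inputs(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 30))
        actual = r.normal(0, 3, size=(3, n))
        predicted = r.normal(0, 3, size=(3, n))
        got = r2_score(actual, predicted).value
        assert got == pytest.approx(brute_force_r2(actual, predicted), abs=1e-12)

    def test_invariant_to_joint_sample_permutation(self, rng):
        actual = rng.standard_normal((3, 40))
        predicted = rng.standard_normal((3, 40))
        perm = rng.permutation(40)
        a = r2_score(actual, predicted).value
        b = r2_score(actual[:, perm], predicted[:, perm]).value
        assert a == pytest.approx(b, abs=1e-12)

    def test_pooled_ratio_not_mean_of_per_dimension_scores(self, rng):
        # one high-variance dimension dominates the pooled denominator
        actual = rng.standard_normal((3, 60))
        actual[0] *= 100
        predicted = actual + rng.standard_normal((3, 60))
        pooled = r2_score(actual, predicted).value
        per_dim = np.mean(
            [brute_force_r2(actual[d : d + 1], predicted[d : d + 1]) for d in range(3)]
        )
        assert abs(pooled - per_dim) > 0.01

    def test_zero_variance_rejected(self):
        flat = np.ones((3, 10))
        with pytest.raises(ValueError, match="variance"):
            r2_score(flat, flat.copy())


def _random_trajectories(rng, names, n=400):
    out = {}
    for nm in names:
        reg = RegionDefinition(nm, ("a", "b", "c"))
        out[nm] = RegionTrajectory(rng.standard_normal((3, n)), reg)
    return out


class TestPairwiseMatrix:
    CFG = TrainConfig(seed=11, iterations=150)

    def test_all_ordered_pairs_filled_diagonal_masked(self, rng):
        trajs = _random_trajectories(rng, ["P", "F", "MCL", "MCR", "MCZ"])
        mat = pairwise_matrix(trajs, self.CFG)
        assert np.all(np.isnan(np.diag(mat.values)))
        assert np.isfinite(mat.offdiag()).all()
        assert mat.offdiag().size == 20

    def test_deterministic_given_seed(self, rng):
        trajs = _random_trajectories(rng, ["A", "B", "C"], n=200)
        m1 = pairwise_matrix(trajs, self.CFG)
        m2 = pairwise_matrix(trajs, self.CFG)
        assert np.array_equal(m1.values, m2.values, equal_nan=True)

    def test_functionally_linked_pair_is_matrix_maximum(self, rng):
        names = ["P", "F", "MCL"]
        trajs = _random_trajectories(rng, names, n=1500)
        # impose A->B functional relation: F = affine(P)
        a = rng.normal(size=(3, 3)) + 0.5 * np.eye(3)
        linked = a @ trajs["P"].values + 0.05 * rng.standard_normal((3, 1500))
        trajs["F"] = RegionTrajectory(linked, trajs["F"].region)
        mat = pairwise_matrix(trajs, TrainConfig(seed=11))
        assert mat.get("P", "F") == np.nanmax(mat.values)
        assert mat.get("P", "F") > 0.8

    def test_symmetrize_takes_directional_maximum(self, rng):
        trajs = _random_trajectories(rng, ["A", "B"], n=200)
        directed = pairwise_matrix(trajs, self.CFG)
        sym = pairwise_matrix(trajs, self.CFG, symmetrize=True)
        expected = max(directed.get("A", "B"), directed.get("B", "A"))
        assert sym.get("A", "B") == expected == sym.get("B", "A")


def _matrix(values, regions, win, corrected=False):
    return ConnectivityMatrix(
        values=np.array(values, dtype=float),
        regions=regions,
        band=THETA,
        window=win,
        subject_id="s00",
        baseline_corrected=corrected,
    )


class TestBaselineCorrect:
    W0 = TimeWindow(-1.0, 0.0)
    W1 = TimeWindow(0.0, 0.5)

    def _matrices(self):
        pre = _matrix([[0, 0.2], [0.3, 0]], ["A", "B"], self.W0)
        post = _matrix([[0, 0.7], [0.1, 0]], ["A", "B"], self.W1)
        return {self.W0: pre, self.W1: post}

    def test_prestimulus_becomes_exactly_zero(self):
        corrected = baseline_correct(self._matrices(), self.W0)
        assert np.all(corrected[self.W0].offdiag() == 0.0)
        assert corrected[self.W0].baseline_corrected

    def test_entrywise_subtraction(self):
        corrected = baseline_correct(self._matrices(), self.W1)
        # using the post window as baseline: 0.7 - 0.7 = 0, pre: 0.2 - 0.7
        assert corrected[self.W0].get("A", "B") == pytest.approx(-0.5)
        assert corrected[self.W1].get("A", "B") == 0.0

    def test_idempotent(self):
        once = baseline_correct(self._matrices(), self.W0)
        twice = baseline_correct(once, self.W0)
        for win in once:
            assert np.array_equal(
                once[win].values, twice[win].values, equal_nan=True
            )

    def test_missing_prestimulus_rejected(self):
        with pytest.raises(KeyError):
            baseline_correct(self._matrices(), TimeWindow(5.0, 6.0))

    def test_region_order_mismatch_rejected(self):
        mats = self._matrices()
        mats[self.W1] = _matrix([[0, 0.7], [0.1, 0]], ["B", "A"], self.W1)
        with pytest.raises(ValueError, match="region order"):
            baseline_correct(mats, self.W0)


class TestSerialization:
    def _matrices(self, rng):
        wins = [TimeWindow(-1.0, 0.0), TimeWindow(0.0, 0.5)]
        return {
            w: _matrix(rng.normal(size=(3, 3)), ["P", "F", "MCZ"], w) for w in wins
        }

    def test_long_csv_round_trip(self, rng, tmp_path):
        mats = self._matrices(rng)
        path = tmp_path / "mats.csv"
        write_matrices_csv(mats, path)
        frame = read_matrices_csv(path)
        rebuilt = frame_to_matrices(frame, band=THETA)
        for win, mat in mats.items():
            assert np.allclose(
                rebuilt[win].values, mat.values, equal_nan=True, atol=1e-12
            )
            assert rebuilt[win].regions == mat.regions

    def test_json_round_trip_lossless(self, rng, tmp_path):
        mats = self._matrices(rng)
        path = tmp_path / "mats.json"
        write_matrices_json(mats, path)
        rebuilt = read_matrices_json(path, band=THETA)
        for win, mat in mats.items():
            assert np.array_equal(rebuilt[win].values, mat.values, equal_nan=True)
            assert rebuilt[win].subject_id == mat.subject_id

    def test_frame_has_expected_columns(self, rng):
        frame = matrices_to_frame(self._matrices(rng))
        assert list(frame.columns) == [
            "subject",
            "band",
            "window_start",
            "window_end",
            "drive",
            "response",
            "r2",
            "corrected",
        ]
        assert len(frame) == 2 * 6
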