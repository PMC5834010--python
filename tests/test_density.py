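"""The KNN density statistic: closed forms, oracles and invariances."""
import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tilquant as tq
from tilquant.density import CellMap, SlideDensitySummary, summaries_to_frame
from tilquant.errors import ContractViolation, ValidationError

UNIT_SQUARE = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])


def brute_force_knn_mean(points: np.ndarray, index: int, k: int) -> float:
    """All-pairs sort oracle, independent of the KD-tree path."""
    d = sorted(
        math.dist(points[index], p) for i, p in enumerate(points) if i != index
    )
    return sum(d[:k]) / k


class TestKnnMeanDistance:
    def test_two_points(self):
        pts = np.array([[0.0, 0], [3.0, 0]])
        assert tq.knn_mean_distance(pts, 0, 1) == 3.0

    def test_unit_square_closed_form(self):
        expected = (1 + 1 + math.sqrt(2)) / 3
        assert tq.knn_mean_distance(UNIT_SQUARE, 0, 3) == pytest.approx(expected,
                                                                        rel=1e-12)

    def test_contracts(self):
        with pytest.raises(ContractViolation):
            tq.knn_mean_distance(np.array([[0.0, 0]]), 0, 1)
        with pytest.raises(ContractViolation):
            tq.knn_mean_distance(UNIT_SQUARE, 0, 4)
        with pytest.raises(ContractViolation):
            tq.knn_mean_distance(UNIT_SQUARE, 0, 0)

    def test_matches_brute_force_everywhere(self, rng):
        pts = rng.uniform(0, 100, size=(60, 2))
        for idx in range(0, 60, 7):
            for k in (1, 5, 59):
                assert tq.knn_mean_distance(pts, idx, k) == pytest.approx(
                    brute_force_knn_mean(pts, idx, k), rel=1e-12
                )


class TestLymphocyteDensity:
    def test_two_point_closed_form(self):
        s = tq.lymphocyte_density(np.array([[0.0, 0], [1.0, 0]]))
        assert s.k_used == 1
        assert s.median_density == pytest.approx(1 / math.pi, rel=1e-12)

    def test_sparse_slide_truncates_k(self):
        pts = np.random.default_rng(0).uniform(0, 50, size=(10, 2))
        s = tq.lymphocyte_density(pts, n_target=50)
        assert s.k_used == 9

    @pytest.mark.parametrize("n", [0, 1])
    def test_below_two_lymphocytes_summary_missing(self, n):
        s = tq.lymphocyte_density(np.zeros((n, 2)))
        assert not s.defined
        assert s.median_density is None

    def test_even_count_median_averages_central_pair(self):
        # collinear points engineered to give four distinct densities
        pts = np.array([[0.0, 0], [1.0, 0], [3.0, 0], [7.0, 0]])
        s = tq.lymphocyte_density(pts, n_target=1, keep_per_cell=True)
        d = np.sort(s.per_lymphocyte_densities)
        assert s.median_density == pytest.approx((d[1] + d[2]) / 2, rel=1e-12)

    def test_kdtree_equals_brute_force_summary(self, rng):
        pts = rng.uniform(0, 500, size=(200, 2))
        s = tq.lymphocyte_density(pts, n_target=50, keep_per_cell=True)
        for idx in (0, 57, 199):
            r = brute_force_knn_mean(pts, idx, 50)
            assert s.per_lymphocyte_densities[idx] == pytest.approx(
                50 / (math.pi * r**2), rel=1e-9
            )

    def test_duplicate_coordinates_excluded_with_warning(self, caplog):
        pts = np.array([[0.0, 0], [0.0, 0], [5.0, 0]])
        with caplog.at_level(logging.WARNING, logger="tilquant.density"):
            s = tq.lymphocyte_density(pts, n_target=2)
        # the two coincident points still have positive mean distance; only a
        # fully degenerate point (all neighbours coincident) is dropped
        assert s.defined
        all_dup = np.zeros((3, 2))
        with caplog.at_level(logging.WARNING, logger="tilquant.density"):
            s2 = tq.lymphocyte_density(all_dup, n_target=2)
        assert not s2.defined
        assert "excluded" in caplog.text

    def test_translation_rotation_invariance(self, rng):
        pts = rng.uniform(0, 300, size=(120, 2))
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        moved = pts @ rot.T + np.array([123.4, -56.7])
        a = tq.lymphocyte_density(pts, keep_per_cell=True)
        b = tq.lymphocyte_density(moved, keep_per_cell=True)
        np.testing.assert_allclose(a.per_lymphocyte_densities,
                                   b.per_lymphocyte_densities, rtol=1e-9)

    def test_scale_covariance(self, rng):
        pts = rng.uniform(0, 300, size=(120, 2))
        c = 3.7
        a = tq.lymphocyte_density(pts, keep_per_cell=True)
        b = tq.lymphocyte_density(pts * c, keep_per_cell=True)
        np.testing.assert_allclose(b.per_lymphocyte_densities,
                                   a.per_lymphocyte_densities / c**2, rtol=1e-9)

    def test_poisson_calibration_constant_regression(self):
        """At 2000 lymphocytes/mm^2 on a 1 mm field with N = 50 the median
        summary is ~2.12 x the true intensity (the average-of-50-NN estimator
        is proportional, not equal, to lambda; value pinned by simulation)."""
        rng = np.random.default_rng(77)
        lam = 2000 / 1e6
        vals = [
            tq.lymphocyte_density(
                rng.uniform(0, 1000, size=(rng.poisson(lam * 1e6), 2))
            ).median_density
            for _ in range(50)
        ]
        assert np.mean(vals) / lam == pytest.approx(2.124, abs=0.04)


class TestDensityChange:
    def _summary(self, v, pid="P1"):
        return SlideDensitySummary("s", 100, 50, v, patient_id=pid)

    def test_arithmetic(self):
        ch = tq.density_change(self._summary(0.1), self._summary(0.4))
        assert ch.delta == pytest.approx(0.3)
        assert ch.log_ratio == pytest.approx(math.log(4), rel=1e-12)

    def test_no_change(self):
        ch = tq.density_change(self._summary(0.2), self._summary(0.2))
        assert ch.delta == 0.0

    def test_missing_propagates(self):
        ch = tq.density_change(self._summary(None), self._summary(0.4))
        assert ch.delta is None and ch.log_ratio is None
        assert ch.pre is not None  # record retained

    def test_mismatched_patients_rejected(self):
        with pytest.raises(ContractViolation):
            tq.density_change(self._summary(0.1, "P1"), self._summary(0.2, "P2"))


class TestRescale:
    def test_examples(self):
        np.testing.assert_allclose(tq.rescale_unit_interval([2, 4, 6]), [0, 0.5, 1])
        np.testing.assert_allclose(tq.rescale_unit_interval([5, 5, 5]), [0, 0, 0])

    def test_empty_rejected(self):
        with pytest.raises(ContractViolation):
            tq.rescale_unit_interval([])
        with pytest.raises(ContractViolation):
            tq.rescale_unit_interval([float("nan")])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, unique=True))
    def test_bounds_and_order_preserved(self, values):
        out = tq.rescale_unit_interval(values)
        assert out.min() == 0.0 and out.max() == 1.0
        # order preserved (weakly: scaling may collapse sub-ulp gaps)
        assert np.all(np.diff(out[np.argsort(values, kind="stable")]) >= 0)


class TestCellMap:
    def test_rejects_out_of_field_and_unknown_class(self):
        frame = pd.DataFrame({"x_um": [10.0], "y_um": [10.0], "class": ["lymphocyte"]})
        tq.CellMap.from_frame("s", frame, 20, 20)  # fine
        with pytest.raises(ValidationError):
            tq.CellMap.from_frame("s", frame, 5, 5)
        bad = frame.assign(**{"class": ["epithelial"]})
        with pytest.raises(ValidationError):
            tq.CellMap.from_frame("s", bad, 20, 20)

    def test_summary_frame_layout(self):
        s = tq.lymphocyte_density(np.array([[0.0, 0], [1.0, 0]]), slide_id="a")
        frame = summaries_to_frame([s, tq.lymphocyte_density(np.zeros((1, 2)),
                                                             slide_id="b")])
        assert list(frame.columns) == ["slide_id", "n_lymphocytes", "k_used",
                                       "median_density_au"]
        assert frame["median_density_au"].isna().tolist() == [False, True]
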