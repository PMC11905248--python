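"""DVH engine, constraint template, discrepancy formula, replanning flag."""

import numpy as np
import pytest

from doseaccum.core import GridDescriptor, ImageVolume
from doseaccum.dvh import (
    DEFAULT_CONSTRAINTS,
    Constraint,
    ConstraintReport,
    ConstraintResult,
    DVHError,
    adaptation_flag,
    compute_dvh,
    dvh_metric,
    evaluate_template,
    percent_volume_discrepancy,
)

GRID_1MM = GridDescriptor((10, 10, 10), (1.0, 1.0, 1.0))


def _vol(data):
    return ImageVolume(np.asarray(data, float).reshape(GRID_1MM.shape), GRID_1MM)


def _sorting_oracle_d_pct(values, voxvol_cc, pct):
    """Minimum dose of the hottest pct% of voxels, by explicit sorting."""
    v = np.sort(values)[::-1]
    n_hot = pct / 100.0 * len(v)
    k = int(np.ceil(n_hot))
    return v[max(k - 1, 0)]


def _sorting_oracle_v_gy(values, gy):
    return 100.0 * np.mean(values >= gy)


class TestComputeDVH:
    def test_uniform_dose_step_curve(self):
        mask = np.ones(GRID_1MM.shape, dtype=bool)
        curve = compute_dvh(_vol(np.full(1000, 10.0)), mask)
        assert curve.total_volume_cc == pytest.approx(1.0)
        assert dvh_metric(curve, "V_Gy", 10.0, "cc") == pytest.approx(1.0)
        assert dvh_metric(curve, "V_Gy", 10.0, "pct") == pytest.approx(100.0)
        assert dvh_metric(curve, "V_Gy", 10.011, "pct") == 0.0

    def test_linear_ramp_median_volumes(self):
        vals = np.linspace(0.0, 40.0, 1000)
        mask = np.ones(GRID_1MM.shape, dtype=bool)
        curve = compute_dvh(_vol(vals), mask)
        assert dvh_metric(curve, "V_Gy", 20.0, "pct") == pytest.approx(50.0, abs=0.5)
        assert dvh_metric(curve, "D_pct", 50.0) == pytest.approx(20.0, abs=0.05)

    def test_total_volume_is_exact_voxel_count(self, small_case):
        mask = small_case.structures["rectum"]
        curve = compute_dvh(small_case.plan_dose, mask)
        assert curve.total_volume_cc == mask.sum() * small_case.grid.voxel_volume_cc

    def test_empty_mask_raises_with_name(self):
        with pytest.raises(DVHError, match="rectum"):
            compute_dvh(_vol(np.zeros(1000)), np.zeros(GRID_1MM.shape, bool), structure="rectum")

    def test_curve_monotone_non_increasing(self, rng):
        mask = np.ones(GRID_1MM.shape, dtype=bool)
        curve = compute_dvh(_vol(rng.uniform(0, 40, 1000)), mask)
        assert np.all(np.diff(curve.cum_volume_cc) <= 0)
        assert curve.cum_volume_cc[0] == curve.total_volume_cc


class TestDVHMetricOracle:
    def test_uniform_prescription_d95(self):
        mask = np.ones(GRID_1MM.shape, dtype=bool)
        curve = compute_dvh(_vol(np.full(1000, 36.25)), mask)
        assert dvh_metric(curve, "D_pct", 95.0) == pytest.approx(36.25, abs=0.005)

    def test_v0_is_total_volume(self, rng):
        mask = np.ones(GRID_1MM.shape, dtype=bool)
        curve = compute_dvh(_vol(rng.uniform(1, 40, 1000)), mask)
        assert dvh_metric(curve, "V_Gy", 0.0, "pct") == pytest.approx(100.0)

    def test_matches_sorting_oracle_on_random_fields(self, rng):
        """Interpolated DVH metrics agree with the brute-force voxel-sorting
        oracle within one bin width on 100 random dose fields."""
        mask = np.ones(GRID_1MM.shape, dtype=bool)
        bin_gy = 0.01
        for _ in range(100):
            values = rng.uniform(0, 40, 1000)
            curve = compute_dvh(_vol(values), mask, bin_gy)
            for pct in (5.0, 50.0, 95.0):
                assert dvh_metric(curve, "D_pct", pct) == pytest.approx(
                    _sorting_oracle_d_pct(values, GRID_1MM.voxel_volume_cc, pct), abs=2 * bin_gy
                )
            for gy in (10.0, 20.0, 35.0):
                assert dvh_metric(curve, "V_Gy", gy, "pct") == pytest.approx(
                    _sorting_oracle_v_gy(values, gy), abs=0.2
                )

    def test_metric_monotonicity(self, rng):
        mask = np.ones(GRID_1MM.shape, dtype=bool)
        curve = compute_dvh(_vol(rng.uniform(0, 40, 1000)), mask)
        d = [dvh_metric(curve, "D_pct", x) for x in (5, 25, 50, 75, 95)]
        assert all(b <= a + 1e-12 for a, b in zip(d, d[1:]))
        v = [dvh_metric(curve, "V_Gy", x, "pct") for x in (5, 15, 25, 35)]
        assert all(b <= a + 1e-12 for a, b in zip(v, v[1:]))

    def test_d_pct_v_gy_consistency(self, rng):
        mask = np.ones(GRID_1MM.shape, dtype=bool)
        curve = compute_dvh(_vol(rng.uniform(0, 40, 1000)), mask)
        for x in (10.0, 50.0, 90.0):
            d = dvh_metric(curve, "D_pct", x)
            assert dvh_metric(curve, "V_Gy", d, "pct") >= x - 0.2

    def test_d_cc_beyond_volume_rejected(self, rng):
        mask = np.ones(GRID_1MM.shape, dtype=bool)
        curve = compute_dvh(_vol(rng.uniform(0, 40, 1000)), mask)  # 1 cc total
        with pytest.raises(DVHError):
            dvh_metric(curve, "D_cc", 5.0)


class TestTemplate:
    def test_phantom_plan_passes_ptv_coverage(self, small_case):
        doses = {n: (small_case.plan_dose, small_case.structures[n]) for n in small_case.structures.names}
        report = evaluate_template(doses)
        row = next(
            r
            for r in report.results
            if r.constraint.structure == "PTV_eval" and r.constraint.arg == 36.25
        )
        assert row.passed

    def test_zero_dose_splits_by_direction(self, small_case):
        zero = ImageVolume(np.zeros(small_case.grid.shape), small_case.grid)
        doses = {n: (zero, small_case.structures[n]) for n in small_case.structures.names}
        report = evaluate_template(doses)
        for r in report.results:
            assert r.passed == (r.constraint.direction == "le")

    def test_forced_rectum_violation_deviation_arithmetic(self):
        """3.5 cc of rectum at >= 34.4 Gy against a 3.00 cc bound fails with
        a +16.7% deviation."""
        grid = GridDescriptor((20, 20, 20), (1.0, 1.0, 1.0))
        mask = np.zeros(grid.shape, dtype=bool)
        mask.ravel()[:5000] = True
        dose = np.zeros(grid.shape)
        dose.ravel()[:3500] = 35.0
        report = evaluate_template(
            {"rectum": (ImageVolume(dose, grid), mask)},
            [Constraint("rectum", "V_Gy", 34.40, 3.00, "le", "cc")],
        )
        r = report.results[0]
        assert not r.passed
        assert r.achieved == pytest.approx(3.5, abs=0.01)
        assert r.deviation_pct == pytest.approx(16.7, abs=0.2)

    def test_missing_structure_reported_not_evaluated(self, small_case):
        doses = {"PTV_eval": (small_case.plan_dose, small_case.structures["PTV_eval"])}
        report = evaluate_template(doses, DEFAULT_CONSTRAINTS)
        missing = [r for r in report.results if not r.evaluated]
        assert missing and all(r.constraint.structure != "PTV_eval" for r in missing)


class TestDiscrepancyAndFlag:
    def test_percent_volume_discrepancy_formula(self):
        assert percent_volume_discrepancy(98.2, 100.0) == pytest.approx(-1.8)
        assert percent_volume_discrepancy(50.0, 50.0) == 0.0
        assert percent_volume_discrepancy(150.0, 100.0) == pytest.approx(50.0)
        with pytest.raises(DVHError):
            percent_volume_discrepancy(1.0, 0.0)

    @staticmethod
    def _report(deviations):
        c = Constraint("PTV_eval", "V_Gy", 36.25, 95.0, "ge", "pct")
        return ConstraintReport(
            results=[ConstraintResult(c, 95.0, d <= 0, d) for d in deviations]
        )

    def test_all_small_deviations_no_flag(self):
        flag, viol = adaptation_flag(self._report([-1.0, 0.5, 2.0]))
        assert not flag and not viol

    def test_single_large_deviation_flags_and_lists(self):
        flag, viol = adaptation_flag(self._report([1.0, 4.0]))
        assert flag
        assert len(viol) == 1 and viol[0].deviation_pct == 4.0

    def test_exactly_three_percent_does_not_flag(self):
        """The trigger fires strictly above the tolerance."""
        flag, _ = adaptation_flag(self._report([3.0]))
        assert not flag
        flag, _ = adaptation_flag(self._report([3.0 + 1e-9]))
        assert flag
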