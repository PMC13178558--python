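"""Spot-intensity calibration: FP threshold, mixture fit, quantification."""

import numpy as np
import pandas as pd
import pytest

from burstfish import (
    DataError,
    IntensityCalibration,
    IntensityCalibrator,
    SpotTable,
    ZINBParams,
    fit_intensity_mixture,
    fp_threshold,
    generate_spot_table,
    quantify_counts,
    sample_zinb,
)


class TestFPThreshold:
    def test_constant_sample(self):
        assert fp_threshold([7.0] * 50) == 7.0

    def test_linear_interpolation_convention(self):
        # sorted 0-based position 999 * 0.999 = 998.001 on values 1..1000
        assert fp_threshold(np.arange(1.0, 1001.0)) == pytest.approx(999.001, abs=1e-9)

    def test_single_value(self):
        assert fp_threshold([42.0]) == 42.0

    def test_empty_control_rejected(self):
        with pytest.raises(DataError):
            fp_threshold([])


class TestMixtureFit:
    def test_single_gaussian_mle_is_near_sample_mean(self):
        rng = np.random.default_rng(0)
        data = rng.normal(100.0, 5.0, 1000)
        comps = fit_intensity_mixture(data, n_components=1, seed=0)
        assert comps[0][1] == pytest.approx(100.0, abs=3 * 5.0 / np.sqrt(1000))

    def test_two_component_recovery(self):
        rng = np.random.default_rng(1)
        data = np.concatenate([rng.normal(100, 8, 2000), rng.normal(200, 8, 2000)])
        comps = fit_intensity_mixture(data, n_components=2, seed=0)
        assert comps[0][1] == pytest.approx(100.0, abs=2.0)
        assert comps[0][1] < comps[1][1]  # ascending mean order

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            fit_intensity_mixture([1.0, 2.0, 3.0, 4.0, 5.0], n_components=2)

    def test_fit_is_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        data = np.concatenate([rng.normal(100, 8, 500), rng.normal(220, 10, 500)])
        assert fit_intensity_mixture(data, 2, seed=3) == fit_intensity_mixture(data, 2, seed=3)


def make_spot_table(rows, cells=None, control=()):
    df = pd.DataFrame(rows, columns=["spot_id", "cell_id", "intensity", "peak_height"])
    roster = None
    if cells is not None:
        roster = pd.DataFrame(
            {"cell_id": cells, "strain": "wt", "condition_uM": 0.0}
        )
    return SpotTable(spots=df, control_intensities=np.asarray(control, float), cells=roster)


class TestQuantifyCounts:
    CAL = IntensityCalibration(fp_threshold=20.0, unit_intensity=100.0, mixture=[])

    def test_methods_division_rule(self):
        table = make_spot_table(
            [("s0", "c0", 95.0, 1.0), ("s1", "c0", 210.0, 1.0)], cells=["c0"]
        )
        out = quantify_counts(table, self.CAL)
        assert out.loc[0, "count"] == 3  # round(305 / 100)

    def test_all_subthreshold_spots_give_zero(self):
        table = make_spot_table(
            [("s0", "c0", 10.0, 1.0), ("s1", "c0", 12.0, 1.0)], cells=["c0"]
        )
        assert quantify_counts(table, self.CAL)["count"].tolist() == [0]

    def test_spotless_roster_cell_gets_zero(self):
        table = make_spot_table([("s0", "c0", 95.0, 1.0)], cells=["c0", "c1"])
        out = quantify_counts(table, self.CAL).set_index("cell_id")
        assert out.loc["c1", "count"] == 0

    def test_raising_threshold_never_raises_counts(self):
        counts = sample_zinb(ZINBParams(0.3, 2.0, 0.7), 200, seed=7)
        table = generate_spot_table(100.0, 0.1, counts, 0, 12.0, seed=8)
        prev = None
        for thr in (0.0, 50.0, 120.0, 250.0, 1000.0):
            cal = IntensityCalibration(fp_threshold=thr, unit_intensity=100.0, mixture=[])
            cur = quantify_counts(table, cal).set_index("cell_id")["count"]
            if prev is not None:
                assert (cur <= prev).all()
            prev = cur

    def test_spot_order_is_irrelevant(self):
        counts = sample_zinb(ZINBParams(0.3, 2.0, 0.7), 100, seed=9)
        table = generate_spot_table(100.0, 0.1, counts, 0, 12.0, seed=10)
        shuffled = SpotTable(
            spots=table.spots.sample(frac=1.0, random_state=3).reset_index(drop=True),
            control_intensities=table.control_intensities,
            cells=table.cells,
        )
        a = quantify_counts(table, self.CAL).sort_values("cell_id").reset_index(drop=True)
        b = quantify_counts(shuffled, self.CAL).sort_values("cell_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestEndToEndRecovery:
    def test_calibrated_pipeline_recovers_true_counts(self):
        """sample -> spots -> calibrate -> quantify reproduces >= 99% of cells.

        Moderate expression, intensity CV 0.10, control population entirely
        below half the unit intensity.
        """
        counts = sample_zinb(ZINBParams(0.5, 2.0, 0.5), 400, seed=21)
        table = generate_spot_table(100.0, 0.10, counts, 1000, 12.0, seed=22)
        cal = IntensityCalibrator(n_components=3, random_state=0).fit(table)
        assert cal.fp_threshold_ < 50.0
        est = cal.transform(table)
        merged = counts.merge(est, on=["cell_id", "strain", "condition_uM"],
                              suffixes=("_true", "_est"))
        assert (merged["count_true"] == merged["count_est"]).mean() >= 0.99
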