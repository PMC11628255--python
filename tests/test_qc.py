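"""Control statistics, Z'-gated QC and the normalization formulas."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lumiqc import (
    AssayConfig,
    ControlStats,
    control_stats,
    cv,
    normalize,
    plate_effect_summary,
    qc_plate,
    s_over_b,
    zprime,
)
from lumiqc.errors import DegenerateControls, MissingControls, ZeroMean
from lumiqc.plate import ROWS


def well_table(neg, pos, samples=(), plate_id="p"):
    rows = []
    wells = iter([f"{r}{c:02d}" for r in ROWS for c in range(1, 25)])
    for role, values in (
        ("negative_control", neg),
        ("positive_control", pos),
        ("sample", samples),
    ):
        for v in values:
            rows.append(
                {"plate_id": plate_id, "assay_id": "a", "well": next(wells),
                 "role": role, "compound_id": "X" if role == "sample" else "",
                 "concentration_um": 1.0 if role == "sample" else None,
                 "replicate_group": "", "raw_signal": float(v)}
            )
    return pd.DataFrame(rows)


class TestControlStats:
    def test_zero_spread_groups(self):
        stats = control_stats(well_table([100, 100], [10, 10]))
        assert (stats.mu_n, stats.sd_n, stats.mu_p, stats.sd_p) == (100, 0, 10, 0)

    def test_sample_sd_uses_n_minus_one(self):
        stats = control_stats(well_table([90, 110], [10, 10]))
        assert stats.mu_n == 100
        assert stats.sd_n == pytest.approx(14.1421, abs=1e-4)

    def test_missing_positive_controls(self):
        with pytest.raises(MissingControls):
            control_stats(well_table([100, 100], []))


class TestFormulas:
    def test_zprime_zero_spread_is_one(self):
        assert zprime(ControlStats(100, 10, 0, 0, 2, 2)) == 1.0

    def test_zprime_hand_value(self):
        assert zprime(ControlStats(100, 10, 5, 2, 4, 4)) == pytest.approx(0.76667, abs=1e-5)

    def test_zprime_degenerate(self):
        with pytest.raises(DegenerateControls):
            zprime(ControlStats(50, 50, 1, 1, 2, 2))

    def test_s_over_b(self):
        assert s_over_b(ControlStats(100, 10, 0, 0, 2, 2)) == 10
        assert s_over_b(ControlStats(136, 1, 0, 0, 2, 2)) == 136

    def test_s_over_b_zero_background(self):
        with pytest.raises(ZeroDivisionError):
            s_over_b(ControlStats(100, 0, 0, 0, 2, 2))

    def test_cv(self):
        assert cv([10, 10, 10]) == 0
        assert cv([8, 12]) == pytest.approx(28.284, abs=1e-3)

    def test_cv_zero_mean(self):
        with pytest.raises(ZeroMean):
            cv([-1, 1])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(1, 1e6), min_size=2, max_size=20),
        st.lists(st.floats(1, 1e6), min_size=2, max_size=20),
    )
    def test_formulas_match_brute_force(self, neg, pos):
        """Implementation agrees with plain-Python re-evaluation."""
        def mean(v):
            return sum(v) / len(v)

        def sd(v):
            m = mean(v)
            return math.sqrt(sum((x - m) ** 2 for x in v) / (len(v) - 1))

        mu_n, mu_p = mean(neg), mean(pos)
        if mu_n == mu_p:
            return
        stats = control_stats(well_table(neg, pos))
        expect_z = 1 - 3 * (sd(pos) + sd(neg)) / abs(mu_n - mu_p)
        assert zprime(stats) == pytest.approx(expect_z, rel=1e-12, abs=1e-12)
        assert s_over_b(stats) == pytest.approx(mu_n / mu_p, rel=1e-12)
        assert cv(neg) == pytest.approx(sd(neg) / mu_n * 100, rel=1e-12)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.floats(10, 1e6), st.floats(0, 9), st.floats(0, 2e6),
    )
    def test_normalize_identities(self, mu_n, mu_p, x):
        """%N_SCh == %N_VALUE - 100 exactly; control fixed points hold."""
        stats = ControlStats(mu_n, mu_p, 1.0, 1.0, 4, 4)
        table = well_table([mu_n, mu_n], [mu_p, mu_p], [x])
        norm = normalize(table, stats)
        np.testing.assert_allclose(
            norm["pct_n_sch"], norm["pct_n_value"] - 100.0, rtol=0, atol=1e-9
        )
        sample = norm[norm["role"] == "sample"].iloc[0]
        expect_inh = (1 - (x - mu_p) / (mu_n - mu_p)) * 100
        assert sample["pct_inhibition"] == pytest.approx(expect_inh, rel=1e-12, abs=1e-9)
        assert sample["pct_n_value"] == pytest.approx(x / mu_n * 100, rel=1e-12)


class TestNormalizeExamples:
    def test_control_fixed_points_and_hand_value(self):
        stats = ControlStats(100, 10, 0, 0, 2, 2)
        norm = normalize(well_table([100, 100], [10, 10], [55]), stats)
        neg = norm[norm["role"] == "negative_control"].iloc[0]
        pos = norm[norm["role"] == "positive_control"].iloc[0]
        sam = norm[norm["role"] == "sample"].iloc[0]
        assert neg["pct_inhibition"] == 0 and neg["pct_n_value"] == 100 and neg["pct_n_sch"] == 0
        assert pos["pct_inhibition"] == 100
        assert sam["pct_inhibition"] == pytest.approx(50, abs=1e-12)
        assert sam["pct_n_value"] == pytest.approx(55, abs=1e-12)
        assert sam["pct_n_sch"] == pytest.approx(-45, abs=1e-12)

    def test_degenerate_controls_rejected(self):
        with pytest.raises(DegenerateControls):
            normalize(well_table([10, 10], [10, 10]), ControlStats(10, 10, 0, 0, 2, 2))


class TestQCPlate:
    def test_tight_controls_pass_untouched(self):
        table = well_table([100, 101, 99, 100], [10, 10, 11, 9])
        qc = qc_plate(table, AssayConfig())
        assert qc.status == "PASS"
        assert qc.outliers_removed == []
        assert qc.zprime_initial >= 0.5

    def test_single_aberrant_control_removed(self):
        table = well_table([100, 101, 99, 100, 40], [10, 10, 10, 10])
        qc = qc_plate(table, AssayConfig())
        assert qc.status == "PASS_AFTER_REMOVAL"
        assert len(qc.outliers_removed) == 1
        # the removed well is the 40-count one (5th negative control well)
        removed_value = table.loc[table["well"].isin(qc.outliers_removed), "raw_signal"]
        assert removed_value.iloc[0] == 40
        assert qc.zprime_final >= 0.5 > qc.zprime_initial

    def test_greedy_matches_exhaustive_leave_one_out(self):
        """Greedy first removal picks the exhaustive best single removal."""
        rng = np.random.default_rng(3)
        neg = list(rng.normal(100, 2, 10)) + [55.0]
        pos = list(rng.normal(10, 1, 10))
        table = well_table(neg, pos)
        qc = qc_plate(table, AssayConfig())

        def z(n, p):
            return 1 - 3 * (np.std(p, ddof=1) + np.std(n, ddof=1)) / abs(np.mean(n) - np.mean(p))

        candidates = [z(np.delete(neg, i), pos) for i in range(len(neg))]
        candidates += [z(neg, np.delete(pos, j)) for j in range(len(pos))]
        best = max(candidates)
        removed_value = table.loc[table["well"].isin(qc.outliers_removed), "raw_signal"].iloc[0]
        assert removed_value == 55.0
        assert qc.zprime_final == pytest.approx(best, rel=1e-12)

    def test_three_aberrant_controls_mean_retest(self):
        table = well_table([100, 100, 101, 99, 100, 5, 4, 6], [10, 10, 10, 10])
        qc = qc_plate(table, AssayConfig(max_outliers=2))
        assert qc.status == "RETEST"

    def test_missing_controls(self):
        with pytest.raises(MissingControls):
            qc_plate(well_table([100], [10, 10]), AssayConfig())


class TestPlateEffect:
    @staticmethod
    def full_plate(values):
        rows = []
        for i, r in enumerate(ROWS):
            for c in range(1, 25):
                rows.append({"well": f"{r}{c:02d}", "pct_inhibition": values[i, c - 1]})
        return pd.DataFrame(rows)

    def test_uniform_plate_has_zero_slopes(self):
        rep = plate_effect_summary(self.full_plate(np.full((16, 24), 7.0)))
        assert rep.row_trend_slope == pytest.approx(0, abs=1e-12)
        assert rep.col_trend_slope == pytest.approx(0, abs=1e-12)
        assert not rep.flagged

    def test_injected_column_gradient_recovered_and_flagged(self):
        ramp = np.tile(np.arange(24.0) * 1.5, (16, 1))
        rep = plate_effect_summary(self.full_plate(ramp))
        assert rep.col_trend_slope == pytest.approx(1.5, rel=1e-9)
        assert rep.row_trend_slope == pytest.approx(0, abs=1e-9)
        assert rep.flagged

    def test_single_hot_well_not_flagged(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(50, 3, size=(16, 24))
        vals[7, 11] += 100
        rep = plate_effect_summary(self.full_plate(vals))
        assert not rep.flagged
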