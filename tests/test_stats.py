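"""Descriptors, group tests and the correlation table."""

import numpy as np
import pandas as pd
import pytest

from vns_chrono import (
    compare_groups,
    compare_paired,
    correlation_table,
    default_subject,
    describe,
    group_report,
    lhs_sample,
    simulate_response_table,
    summarize_subject,
)
from vns_chrono.io import ranges_for
from vns_chrono.stats import DegenerateDataError


class TestDescribe:
    def test_heavy_tailed_gets_iqr(self):
        x = np.random.default_rng(0).standard_cauchy(500)
        d = describe(x)
        assert d.dispersion_kind == "iqr"
        q1, q3 = np.percentile(x, [25, 75])
        assert d.dispersion == pytest.approx(q3 - q1)

    def test_normal_usually_gets_sd(self):
        kinds = [
            describe(np.random.default_rng(seed).normal(size=100)).dispersion_kind
            for seed in range(100)
        ]
        assert kinds.count("sd") >= 90

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateDataError):
            describe([1.0, 1.0, 1.0])

    def test_too_few_values_rejected(self):
        with pytest.raises(DegenerateDataError):
            describe([1.0, 2.0])


class TestCompareGroups:
    def test_identical_groups_null_result(self):
        h, p = compare_groups([[1.0, 1.0, 1.0], [1.0, 1.0], [1.0, 1.0, 1.0]])
        assert h == 0.0 and p == 1.0

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(mu, 1.0, 20) for mu in (0.0, 3.0, 6.0)]
        h, p = compare_groups(groups)
        assert p < 1e-3

    def test_input_validation(self):
        with pytest.raises(ValueError):
            compare_groups([[1.0, 2.0]])
        with pytest.raises(ValueError):
            compare_groups([[1.0, 2.0], [3.0]])


class TestComparePaired:
    def test_constant_drop_detected(self):
        rng = np.random.default_rng(2)
        hr_bl = rng.normal(150, 5, 20)
        w, p = compare_paired(hr_bl, hr_bl - 10.0)
        assert p < 1e-3

    def test_all_zero_differences_rejected(self):
        x = np.linspace(100, 120, 10)
        with pytest.raises(DegenerateDataError):
            compare_paired(x, x.copy())

    def test_length_checks(self):
        with pytest.raises(ValueError):
            compare_paired([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            compare_paired([1, 2, 3], [4, 5, 6])


def toy_responses(x, y, cond="vagotomy"):
    n = len(x)
    return pd.DataFrame(
        {
            "condition": cond,
            "intensity_mA": x,
            "pulse_width_us": np.ones(n),
            "num_pulses": np.ones(n),
            "frequency_Hz": np.ones(n),
            "delay_ms": np.ones(n),
            "charge_uC": x * 1e-3,
            "delta_hr": y,
        }
    )


class TestCorrelationTable:
    def test_perfect_monotone_association(self):
        x = np.linspace(0.2, 2.0, 20)
        ct = correlation_table(toy_responses(x, x**2)).set_index("predictor")
        assert ct.loc["charge_uC", "r"] == pytest.approx(1.0)
        assert ct.loc["intensity_mA", "r"] == pytest.approx(1.0)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.2, 2.0, 30)
        y = np.sin(x) + 0.1 * rng.normal(size=30)
        r_pos = correlation_table(toy_responses(x, y)).set_index("predictor").loc[
            "intensity_mA", "r"
        ]
        r_neg = correlation_table(toy_responses(x, -y)).set_index("predictor").loc[
            "intensity_mA", "r"
        ]
        assert r_neg == pytest.approx(-r_pos)

    def test_constant_predictor_reported_missing(self):
        x = np.linspace(0.2, 2.0, 12)
        ct = correlation_table(toy_responses(x, x)).set_index("predictor")
        assert np.isnan(ct.loc["frequency_Hz", "r"])
        assert not np.isnan(ct.loc["intensity_mA", "r"])

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.5, 2.0, 40)
        y = x + rng.normal(0, 0.3, 40)
        r1 = correlation_table(toy_responses(x, y)).set_index("predictor").loc[
            "intensity_mA", "r"
        ]
        r2 = correlation_table(toy_responses(np.exp(x), y)).set_index("predictor").loc[
            "intensity_mA", "r"
        ]
        assert r1 == pytest.approx(r2)

    def test_min_records_enforced(self):
        x = np.linspace(0.2, 2.0, 4)
        with pytest.raises(ValueError, match="fewer"):
            correlation_table(toy_responses(x, x))

    def test_all_p_values_in_unit_interval(self):
        d = lhs_sample(ranges_for("vagotomy"), 30, seed=6)
        resp = simulate_response_table(default_subject("vagotomy"), d, seed=6)
        ct = correlation_table(resp)
        assert ct["p"].dropna().between(0, 1).all()


class TestGroupReport:
    def test_report_structure_and_tests(self):
        frames = []
        summaries = []
        for state in ("intact", "vagotomy"):
            d = lhs_sample(ranges_for(state), 30, seed=8)
            for i in range(3):
                m = default_subject(state, seed=i)
                resp = simulate_response_table(m, d, subject_id=f"{state}_{i}", seed=10 + i)
                frames.append(resp)
                s = summarize_subject(f"{state}_{i}", state, resp)
                summaries.append(
                    {
                        "subject_id": s.subject_id,
                        "condition": state,
                        "dhr_max": s.dhr_max,
                        "q_thr": s.q_thr,
                        "q_at_dhr_max": s.q_at_dhr_max,
                        "q_norm_at_dhr_max": s.q_norm_at_dhr_max,
                    }
                )
        responses = pd.concat(frames, ignore_index=True)
        report = group_report(responses, pd.DataFrame(summaries))
        assert set(report.columns) == {
            "variable",
            "condition",
            "center",
            "dispersion",
            "dispersion_kind",
            "test",
            "stat",
            "p",
        }
        wil = report[report["test"] == "wilcoxon"]
        assert len(wil) == 2
        # stimulation lowers heart rate: strongly significant within state
        assert (wil["p"] < 1e-3).all()
        kw = report[(report["variable"] == "hr_bl_bpm") & (report["test"] == "kruskal")]
        assert kw["stat"].nunique() == 1  # one H across conditions per variable
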