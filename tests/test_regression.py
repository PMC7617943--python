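"""Two-stage regressions and JZS Bayes factors."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

import forcematch as fm
from forcematch.regression import DEFAULT_JZS_SCALE


def _jzs_gintegral_oracle(t, n, r=DEFAULT_JZS_SCALE):
    """Independent JZS representation: inverse-chi^2 mixture over g."""
    df = n - 1

    def num(g):
        a = 1 + n * g * r * r
        return (
            a**-0.5
            * (1 + t * t / (a * df)) ** (-(df + 1) / 2)
            * (2 * np.pi) ** -0.5
            * g**-1.5
            * np.exp(-1 / (2 * g))
        )

    val, _ = integrate.quad(num, 0, np.inf, limit=400)
    return val / (1 + t * t / df) ** (-(df + 1) / 2)


class TestJzsBayesFactor:
    def test_null_supported_at_t_zero(self):
        assert fm.jzs_bf_onesample(0.0, 20) < 1.0

    def test_large_t_strong_evidence(self):
        assert fm.jzs_bf_onesample(5.0, 20) > 10.0
        assert fm.jzs_bf_onesample(5.0, 20) == pytest.approx(341.439, rel=1e-4)

    @pytest.mark.parametrize("t", [0.0, 1.0, 2.0, 3.0, 5.0])
    def test_matches_independent_oracle(self, t):
        mine = fm.jzs_bf_onesample(t, 20)
        assert mine == pytest.approx(_jzs_gintegral_oracle(t, 20), rel=1e-6)

    def test_monotone_in_t_and_null_sharpens_with_n(self):
        bfs = [fm.jzs_bf_onesample(t, 20) for t in (0.0, 1.0, 2.0, 3.0)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))
        nulls = [fm.jzs_bf_onesample(0.0, n) for n in (5, 20, 80)]
        assert all(a > b for a, b in zip(nulls, nulls[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fm.jzs_bf_onesample(np.inf, 20)
        with pytest.raises(ValueError):
            fm.jzs_bf_onesample(1.0, 1)


def _summaries(slopes, intercepts, levels=(1.0, 2.0, 3.0), condition="direct"):
    rows = []
    for i, (a, b) in enumerate(zip(slopes, intercepts)):
        for lev in levels:
            rows.append(
                {
                    "participant_id": f"P{i:02d}",
                    "subgroup": "g",
                    "condition": condition,
                    "gain": 1.0,
                    "target_force": lev,
                    "n": 6,
                    "mean_match": a * lev + b,
                    "sd_match": 0.1 * (a * lev + b),
                }
            )
    return pd.DataFrame(rows)


class TestPerParticipantFit:
    def test_exact_line_recovered(self):
        tab = fm.per_participant_fit(_summaries([1.2], [0.3]), y="mean", x="target")
        assert tab["slope"].iloc[0] == pytest.approx(1.2)
        assert tab["intercept"].iloc[0] == pytest.approx(0.3)
        assert tab["r2"].iloc[0] == pytest.approx(1.0)

    def test_constant_y_zero_slope(self):
        tab = fm.per_participant_fit(_summaries([0.0], [2.0]), y="mean", x="target")
        assert tab["slope"].iloc[0] == pytest.approx(0.0)

    def test_too_few_levels_raises(self):
        s = _summaries([1.0], [0.0], levels=(2.0,))
        with pytest.raises(ValueError, match="fewer than 2"):
            fm.per_participant_fit(s, y="mean", x="target")

    def test_direct_vs_indirect_pairing(self):
        d = _summaries([1.6], [0.0], condition="direct")
        i = _summaries([1.0], [0.0], condition="indirect")
        tab = fm.per_participant_fit(pd.concat([d, i]), y="mean", x="indirect_mean")
        assert tab["slope"].iloc[0] == pytest.approx(1.6)


class TestPopulationRegression:
    def test_null_data_favors_null(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(20)],
                "slope": 1.0 + rng.normal(0, 0.05, 20),
                "intercept": rng.normal(0, 0.05, 20),
                "r2": 1.0,
            }
        )
        res = fm.population_regression(tab, slope_ref=1.0, intercept_ref=0.0)
        assert res.bf10_slope < 1.0
        assert res.slope_ci95[0] <= res.slope <= res.slope_ci95[1]
        assert res.intercept_ci95[0] <= res.intercept <= res.intercept_ci95[1]

    def test_large_offset_gives_decisive_bf(self):
        rng = np.random.default_rng(1)
        slopes = 1.0 + 0.5 + rng.normal(0, 0.1, 20)  # 5 SDs above the reference
        tab = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(20)],
                "slope": slopes,
                "intercept": rng.normal(0, 0.1, 20),
                "r2": 1.0,
            }
        )
        res = fm.population_regression(tab, slope_ref=1.0)
        assert res.bf10_slope > 100.0


class TestConditionContrast:
    def test_identical_conditions(self):
        rng = np.random.default_rng(2)
        tab = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(15)],
                "slope": rng.normal(1.0, 0.2, 15),
                "intercept": rng.normal(0.0, 0.2, 15),
            }
        )
        res = fm.condition_contrast(tab, tab.copy())
        assert res["mean_difference"] == 0.0
        assert res["bf10"] < 1.0

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(3)
        base = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(15)],
                "slope": rng.normal(1.5, 0.2, 15),
                "intercept": np.zeros(15),
            }
        )
        other = base.assign(slope=rng.normal(1.0, 0.2, 15))
        ab = fm.condition_contrast(base, other)
        ba = fm.condition_contrast(other, base)
        assert ab["mean_difference"] == pytest.approx(-ba["mean_difference"])
        assert ab["bf10"] == pytest.approx(ba["bf10"], rel=1e-9)

    def test_participant_mismatch_raises(self):
        a = pd.DataFrame({"participant_id": ["x"], "slope": [1.0], "intercept": [0.0]})
        b = pd.DataFrame({"participant_id": ["y"], "slope": [1.0], "intercept": [0.0]})
        with pytest.raises(ValueError, match="participant"):
            fm.condition_contrast(a, b)


class TestOnSyntheticCohort:
    def test_direct_vs_indirect_slope_near_population_mean_K(self, divisive_cohort):
        """The direct-vs-indirect regression slope estimates mean_K."""
        summ = fm.summarize_levels(divisive_cohort[0])
        tab = fm.per_participant_fit(summ, y="mean", x="indirect_mean")
        assert 1.4 < tab["slope"].median() < 1.8

    def test_divisive_regression_signatures(self, divisive_cohort):
        """Direct mean-vs-target slopes exceed indirect; same for SD-vs-mean."""
        summ = fm.summarize_levels(divisive_cohort[0])
        d_mean = fm.per_participant_fit(summ, y="mean", x="target", condition="direct")
        i_mean = fm.per_participant_fit(summ, y="mean", x="target", condition="indirect")
        assert d_mean["slope"].mean() > i_mean["slope"].mean()
        d_sd = fm.per_participant_fit(summ, y="sd", x="mean_match", condition="direct")
        i_sd = fm.per_participant_fit(summ, y="sd", x="mean_match", condition="indirect")
        res = fm.condition_contrast(d_sd, i_sd, quantity="slope")
        assert res["mean_difference"] > 0
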