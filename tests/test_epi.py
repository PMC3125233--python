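import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from pcenet.epi import (SmoothCurve, TwoByTwo, confounder_screen, crude_or,
                        exposure_crosstab, fit_logistic, loess_logit,
                        run_latency_table, select_cutpoint,
                        wilcoxon_signed_rank, NO_CUTPOINT)
from pcenet.errors import ParameterError, SmoothingError
from pcenet.exposure import control_percentiles


class TestCrudeOR:
    def test_symmetric_table_is_null(self):
        r = crude_or(TwoByTwo(10, 10, 10, 10))
        assert r.oddsratio == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high

    def test_known_arithmetic(self):
        r = crude_or(TwoByTwo(20, 10, 10, 20))
        assert r.oddsratio == pytest.approx(4.0)
        se = math.sqrt(1 / 20 + 1 / 10 + 1 / 10 + 1 / 20)
        assert r.ci_low == pytest.approx(math.exp(math.log(4) - 1.96 * se),
                                         rel=1e-3)

    def test_zero_cell_undefined(self):
        r = crude_or(TwoByTwo(0, 10, 10, 10))
        assert not r.defined and math.isnan(r.oddsratio)

    def test_scaling_cells_preserves_or_and_narrows_ci(self):
        base = crude_or(TwoByTwo(12, 9, 30, 40))
        big = crude_or(TwoByTwo(120, 90, 300, 400))
        assert big.oddsratio == pytest.approx(base.oddsratio)
        assert (big.ci_high - big.ci_low) < (base.ci_high - base.ci_low)

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            TwoByTwo(-1, 1, 1, 1)


class TestFitLogistic:
    def test_equals_crude_or_on_two_by_two(self):
        """Saturated single-covariate logistic equals the 2x2 odds ratio."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b, c, d = rng.integers(5, 80, size=4)
            y = np.repeat([1, 0, 1, 0], [a, b, c, d])
            x = np.repeat([1.0, 1.0, 0.0, 0.0], [a, b, c, d])
            fit = fit_logistic(y, pd.DataFrame({"exposed": x}),
                               exposure="exposed")
            expected = crude_or(TwoByTwo(a, b, c, d)).oddsratio
            assert fit.aor().oddsratio == pytest.approx(expected, abs=1e-8,
                                                        rel=1e-8)

    def test_ci_covers_known_effect(self):
        rng = np.random.default_rng(12)
        n = 2000
        x = rng.binomial(1, 0.3, n).astype(float)
        z = rng.normal(size=n)
        p = expit(-0.5 + math.log(2.0) * x + 0.3 * z)
        y = rng.random(n) < p
        fit = fit_logistic(y, pd.DataFrame({"x": x, "z": z}), exposure="x")
        r = fit.aor()
        assert r.ci_low < 2.0 < r.ci_high

    def test_constant_exposure_column_raises(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        with pytest.raises(ParameterError, match="singular|constant"):
            fit_logistic(y, pd.DataFrame({"x": np.zeros(6)}))

    def test_separation_detected(self):
        y = np.array([0] * 20 + [1] * 20)
        x = y.astype(float)
        with pytest.raises(ParameterError):
            fit_logistic(y, pd.DataFrame({"x": x}), exposure="x")


class TestConfounderScreen:
    @staticmethod
    def simulate(n=4000, seed=1):
        rng = np.random.default_rng(seed)
        exposure = rng.binomial(1, 0.4, n).astype(float)
        # strong confounder: associated with exposure and outcome
        conf = (0.6 * exposure + rng.normal(size=n) > 0.5).astype(float)
        noise = rng.binomial(1, 0.5, n).astype(float)  # independent
        p = expit(-1.0 + 0.4 * exposure + 1.2 * conf)
        y = rng.random(n) < p
        core = pd.DataFrame({"exposed": exposure})
        cands = pd.DataFrame({"conf": conf, "noise": noise})
        return y, core, cands

    def test_independent_candidate_not_kept_strong_kept(self):
        y, core, cands = self.simulate()
        kept, table = confounder_screen(y, "exposed", core, cands)
        assert kept == ["conf"]
        noise_row = table[table.candidate == "noise"].iloc[0]
        assert noise_row.rel_change < 0.05

    def test_zero_threshold_keeps_everything(self):
        y, core, cands = self.simulate()
        kept, _ = confounder_screen(y, "exposed", core, cands, threshold=0.0)
        assert kept == ["conf", "noise"]


class TestLoessAndCutpoint:
    @staticmethod
    def step_data(n=3000, seed=5, step_at=35.0, p_lo=0.2, p_hi=0.4):
        rng = np.random.default_rng(seed)
        rdd = rng.uniform(0, 100, n)
        y = rng.random(n) < np.where(rdd > step_at, p_hi, p_lo)
        return rdd, y.astype(float)

    def test_constant_risk_gives_flat_curve(self):
        # exactly half the subjects are cases in every RDD neighborhood
        rng = np.random.default_rng(2)
        rdd = np.sort(rng.uniform(0, 100, 4000))
        y = (np.arange(4000) % 2).astype(float)
        curve = loess_logit(rdd, y, span=0.3)
        assert np.all(np.abs(curve.smoothed_logit) < 0.1)

    def test_step_risk_onset_detected_near_step(self):
        rdd, y = self.step_data()
        curve = loess_logit(rdd, y, span=0.2)
        cut = select_cutpoint(curve)
        assert cut is not NO_CUTPOINT
        assert 25.0 <= cut <= 45.0

    def test_onset_stable_across_spans(self):
        rdd, y = self.step_data()
        cuts = [select_cutpoint(loess_logit(rdd, y, span=s))
                for s in (0.1, 0.2, 0.3)]
        assert all(c is not NO_CUTPOINT for c in cuts)
        assert max(cuts) - min(cuts) <= 10.0

    def test_strictly_increasing_curve_returns_first_point(self):
        grid = np.linspace(0, 100, 50)
        curve = SmoothCurve(0.2, grid, 0.01 * grid)
        assert select_cutpoint(curve) == grid[0]

    def test_flat_curve_returns_sentinel(self):
        grid = np.linspace(0, 100, 50)
        curve = SmoothCurve(0.2, grid, np.zeros(50))
        assert select_cutpoint(curve) is NO_CUTPOINT

    def test_decreasing_curve_returns_sentinel(self):
        grid = np.linspace(0, 100, 50)
        curve = SmoothCurve(0.2, grid, -0.05 * grid)
        assert select_cutpoint(curve) is NO_CUTPOINT

    def test_span_bounds_enforced(self):
        rdd, y = self.step_data(n=200)
        with pytest.raises(ParameterError):
            loess_logit(rdd, y, span=0.01)
        with pytest.raises(SmoothingError):
            loess_logit(rdd[:20], y[:20], span=0.3)


class TestWilcoxon:
    def test_identical_vectors_flagged(self):
        w, p, flagged = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert flagged and p == 1.0

    def test_uniform_shift_is_significant(self):
        a = np.arange(100, dtype=float)
        w, p, flagged = wilcoxon_signed_rank(a, a + 1)
        assert not flagged
        assert p < 1e-4

    def test_matches_exhaustive_enumeration_n10(self):
        """Independent oracle: enumerate all 2^n sign assignments."""
        rng = np.random.default_rng(9)
        for trial in range(5):
            d = rng.normal(size=10)
            d[np.abs(d) < 1e-6] = 0.5
            ranks = stats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            dist = []
            for signs in itertools.product([0, 1], repeat=10):
                dist.append(sum(r for s, r in zip(signs, ranks) if s))
            dist = np.array(dist)
            p_expect = min(1.0, 2 * min((dist <= w_obs).mean(),
                                        (dist >= w_obs).mean()))
            w, p, _ = wilcoxon_signed_rank(d, np.zeros(10))
            assert w == pytest.approx(w_obs)
            assert p == pytest.approx(p_expect, rel=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=15)
        b = a + rng.normal(0.3, 1.0, size=15)
        w, p, _ = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, mode="exact")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_large_n(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=200)
        b = a + rng.normal(0.1, 1.0, size=200)
        w, p, _ = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, mode="approx", correction=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ParameterError):
            wilcoxon_signed_rank([1, 2], [1])


def _toy_cohort(n=600, seed=0):
    rng = np.random.default_rng(seed)
    cum = np.where(rng.random(n) < 0.5, 0.0, rng.lognormal(1, 1, n))
    subjects = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "status": np.where(rng.random(n) < 0.45, "case", "control"),
        "reference_year": rng.integers(1983, 1994, n),
        "age": rng.normal(60, 10, n).round(),
        "vital_status": rng.binomial(1, 0.15, n),
        "family_history": rng.binomial(1, 0.1, n),
        "personal_history": rng.binomial(1, 0.03, n),
        "age_first_birth": rng.normal(25, 5, n).round(),
        "occupational_pce": rng.binomial(1, 0.13, n),
        "study_origin": rng.binomial(1, 0.5, n),
        "bottled_water": rng.binomial(1, 0.22, n),
    })
    rows = []
    for L in (0, 5, 19):
        factor = {0: 1.0, 5: 0.8, 19: 0.0}[L]
        c = cum * factor
        rows.append(pd.DataFrame({
            "subject_id": subjects.subject_id, "latency": L,
            "cumulative": c, "peak": c / 5, "duration": (c > 0) * 3,
            "ever": c > 0}))
    return subjects, pd.concat(rows, ignore_index=True)


class TestRunLatencyTable:
    def test_rows_and_internal_consistency(self):
        subjects, metrics = _toy_cohort()
        ctrl = subjects.status == "control"
        exposed_ctrl = metrics[(metrics.latency == 0) & metrics.ever][
            "subject_id"].isin(subjects[ctrl].subject_id)
        vals = metrics[(metrics.latency == 0) & metrics.ever][exposed_ctrl][
            "cumulative"]
        cuts = {L: control_percentiles(vals) for L in (0, 5, 19)}
        table = run_latency_table(subjects, metrics, cuts,
                                  latencies=(0, 5, 19))
        assert set(table.latency) == {0, 5, 19}
        assert (table.groupby("latency").size() == 5).all()

        # crude OR in the table equals crude_or on its own cells
        row = table[(table.latency == 0) & (table.category == "gt_p90")]
        t = TwoByTwo(int(row.cases.iloc[0]), int(row.controls.iloc[0]),
                     int(row.ref_cases.iloc[0]),
                     int(row.ref_controls.iloc[0]))
        assert row.cor.iloc[0] == pytest.approx(crude_or(t).oddsratio)

    def test_empty_latency_yields_undefined_cells_without_crash(self):
        subjects, metrics = _toy_cohort()
        cuts = {L: control_percentiles([1, 2, 3, 4, 5] * 3)
                for L in (0, 19)}
        table = run_latency_table(subjects, metrics, cuts, latencies=(0, 19))
        l19 = table[table.latency == 19]
        assert l19.cases.sum() == 0
        assert l19.cor.isna().all()

    def test_unknown_latency_rejected(self):
        subjects, metrics = _toy_cohort()
        cuts = {7: control_percentiles([1, 2, 3])}
        with pytest.raises(ParameterError):
            run_latency_table(subjects, metrics, cuts, latencies=(7,))

    def test_bottled_water_stratification_partitions_counts(self):
        subjects, metrics = _toy_cohort()
        cuts = {L: control_percentiles([1, 2, 3, 4, 5] * 3)
                for L in (0, 5, 19)}
        whole = run_latency_table(subjects, metrics, cuts,
                                  latencies=(0,), covariates=())
        strat = run_latency_table(
            subjects, metrics, cuts, latencies=(0,), covariates=(),
            stratum=subjects.set_index("subject_id")["bottled_water"])
        merged = strat.groupby("category")[["cases", "controls"]].sum()
        for cat in merged.index:
            w = whole[whole.category == cat]
            assert merged.loc[cat, "cases"] == w.cases.iloc[0]
            assert merged.loc[cat, "controls"] == w.controls.iloc[0]


def test_exposure_crosstab_row_percentages():
    a = ["unexposed"] * 6 + ["low"] * 4
    b = ["unexposed"] * 3 + ["low"] * 3 + ["low"] * 4
    counts, pct = exposure_crosstab(a, b, order=["unexposed", "low"])
    assert counts.loc["unexposed", "unexposed"] == 3
    assert pct.loc["unexposed", "unexposed"] == 50.0
    assert pct.loc["low", "low"] == 100.0
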