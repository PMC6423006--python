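import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from recurrates import (
    CountingData,
    EventHistory,
    WeibullPoissonModel,
    counting_data_from_cohort,
    fit_marginal,
    fit_partially_conditional,
    simulate_poisson_cohort,
    to_counting_data,
    wald_ci,
)
from recurrates.fit import score_info_residuals

from conftest import brute_breslow, brute_score, brute_subject_residuals


class TestToCountingData:
    def test_single_event_history(self):
        h = EventHistory(1, 1.0, 0.0, 1.0, np.array([0.5]))
        d = to_counting_data([h])
        df = d.to_dataframe()
        assert df[["start", "stop", "status", "stratum"]].values.tolist() == [
            [0.0, 0.5, 1, 1],
            [0.5, 1.0, 0, 2],
        ]

    def test_strata_increment(self):
        h = EventHistory(1, 0.0, 0.0, 1.0, np.array([0.25, 0.75]))
        d = to_counting_data([h])
        assert d.stratum.tolist() == [1, 2, 3]

    def test_pooling_caps_strata(self):
        h = EventHistory(1, 0.0, 0.0, 1.0, np.array([0.1, 0.2, 0.3, 0.4, 0.5]))
        d = to_counting_data([h], pool_stratum_at=4)
        assert d.stratum.tolist() == [1, 2, 3, 4, 4, 4]

    def test_event_beyond_c_rejected(self):
        with pytest.raises(ValueError):
            EventHistory(1, 0.0, 0.0, 1.0, np.array([1.5]))

    def test_cohort_builder_matches_history_builder(self, random_histories):
        ref = to_counting_data(random_histories)
        x = np.array([h.x for h in random_histories])
        z = np.array([h.z for h in random_histories])
        c = np.array([h.c for h in random_histories])
        subj = np.concatenate(
            [np.full(h.event_times.size, i) for i, h in enumerate(random_histories)]
        ).astype(np.int64)
        times = np.concatenate([h.event_times for h in random_histories])
        d = counting_data_from_cohort(x, z, c, subj, times)
        assert np.allclose(d.start, ref.start)
        assert np.allclose(d.stop, ref.stop)
        assert np.array_equal(d.status, ref.status)
        assert np.array_equal(d.stratum, ref.stratum)
        assert np.allclose(d.covariates, ref.covariates)

    def test_cohort_builder_event_at_c(self):
        # final event exactly at c: the zero-length censored row is dropped
        x = np.array([1.0])
        c = np.array([1.0])
        d = counting_data_from_cohort(
            x, None, c, np.array([0]), np.array([1.0])
        )
        assert d.n_rows == 1
        assert d.status.tolist() == [1]


class TestMarginalFit:
    def test_toy4_closed_form(self, toy4_data):
        fit = fit_marginal(toy4_data, ["x"])
        assert fit.converged
        assert fit.beta[0] == pytest.approx(math.log(0.5), abs=1e-8)

    def test_toy4_grid_search_oracle(self, toy4_data):
        root = brentq(
            lambda b: brute_score(toy4_data, ["x"], [b], stratified=False)[0],
            -5.0,
            5.0,
            xtol=1e-12,
        )
        fit = fit_marginal(toy4_data, ["x"])
        assert fit.beta[0] == pytest.approx(root, abs=1e-8)

    def test_symmetry_gives_zero(self):
        hs = [
            EventHistory(1, 1.0, 0.0, 1.0, np.array([0.4])),
            EventHistory(2, 0.0, 0.0, 1.0, np.array([0.6])),
        ]
        fit = fit_marginal(to_counting_data(hs), ["x"])
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_no_events_raises(self):
        hs = [EventHistory(1, 1.0, 0.0, 1.0, np.array([]))]
        with pytest.raises(ValueError):
            fit_marginal(to_counting_data(hs), ["x"])

    def test_score_norm_small_when_converged(self, random_histories):
        fit = fit_marginal(to_counting_data(random_histories), ["x"])
        assert fit.converged
        assert fit.score_norm < 1e-8

    def test_separation_flagged(self):
        # all events in the x=1 arm: monotone score, no finite root
        hs = [
            EventHistory(1, 1.0, 0.0, 1.0, np.array([0.2, 0.5])),
            EventHistory(2, 0.0, 0.0, 1.0, np.array([])),
        ]
        fit = fit_marginal(to_counting_data(hs), ["x"])
        assert not fit.converged

    def test_parameter_recovery_correctly_specified(self):
        # mean of (eta_hat, zeta_hat) over replicates matches the truth
        eta, zeta = math.log(0.75), math.log(1.5)
        model = WeibullPoissonModel(lam=2.0 ** 0.8, kappa=1.25, eta=eta, zeta=zeta)
        rng = np.random.default_rng(77)
        n = 1000
        betas = []
        for _ in range(30):
            x = (rng.random(n) < 0.5).astype(float)
            z = (rng.random(n) < 0.25).astype(float)
            c = np.ones(n)
            es, et = simulate_poisson_cohort(model, x, z, c, rng)
            data = counting_data_from_cohort(x, z, c, es, et)
            betas.append(fit_marginal(data, ["x", "z"]).beta)
        mean = np.mean(betas, axis=0)
        sd = np.std(betas, axis=0) / math.sqrt(len(betas))
        assert abs(mean[0] - eta) < 3 * sd[0]
        assert abs(mean[1] - zeta) < 3 * sd[1]


class TestPartiallyConditionalFit:
    def test_toy4_closed_form(self, toy4_data):
        fit = fit_partially_conditional(toy4_data, ["x"])
        assert fit.converged
        expected = math.log((-1.0 + math.sqrt(17.0)) / 8.0)
        assert fit.beta[0] == pytest.approx(expected, abs=1e-8)

    def test_toy4_grid_search_oracle(self, toy4_data):
        root = brentq(
            lambda b: brute_score(toy4_data, ["x"], [b], stratified=True)[0],
            -5.0,
            5.0,
            xtol=1e-12,
        )
        fit = fit_partially_conditional(toy4_data, ["x"])
        assert fit.beta[0] == pytest.approx(root, abs=1e-8)

    def test_single_stratum_equals_marginal(self):
        # survival-type data (follow-up ends at the single event): only
        # stratum 1 exists, so the stratified score reduces to the marginal
        hs = [
            EventHistory(1, 1.0, 0.0, 0.3, np.array([0.3])),
            EventHistory(2, 1.0, 0.0, 1.0, np.array([])),
            EventHistory(3, 0.0, 0.0, 0.7, np.array([0.7])),
            EventHistory(4, 0.0, 0.0, 0.9, np.array([0.9])),
        ]
        d = to_counting_data(hs)
        assert set(d.stratum) == {1}
        fm = fit_marginal(d, ["x"])
        fp = fit_partially_conditional(d, ["x"])
        assert fp.beta[0] == pytest.approx(fm.beta[0], abs=1e-9)

    def test_per_stratum_baselines(self, toy4_data):
        fit = fit_partially_conditional(toy4_data, ["x"])
        assert set(fit.baseline) == {1, 2}
        t1, d1 = fit.baseline[1]
        assert t1.tolist() == [0.25, 0.5]
        assert np.all(d1 > 0)


class TestScoreEngineAgainstBruteForce:
    @pytest.mark.parametrize("stratified", [False, True])
    @pytest.mark.parametrize("beta", [0.0, -0.4, 0.8])
    def test_score_matches(self, random_histories, stratified, beta):
        d = to_counting_data(random_histories)
        score, _, _ = score_info_residuals(
            d, ["x"], [beta], pooled=not stratified
        )
        expected = brute_score(d, ["x"], [beta], stratified=stratified)
        assert score == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("stratified", [False, True])
    def test_residuals_match_brute_force(self, random_histories, stratified):
        d = to_counting_data(random_histories)
        beta = [-0.3]
        _, _, resid = score_info_residuals(d, ["x"], beta, pooled=not stratified)
        expected = brute_subject_residuals(d, ["x"], beta, stratified=stratified)
        assert resid == pytest.approx(expected, abs=1e-10)

    def test_residuals_sum_to_score(self, random_histories):
        d = to_counting_data(random_histories)
        score, _, resid = score_info_residuals(d, ["x", "z"], [0.2, -0.1], pooled=True)
        assert resid.sum(axis=0) == pytest.approx(score, abs=1e-9)

    def test_information_matches_finite_difference(self, random_histories):
        d = to_counting_data(random_histories)
        beta, h = 0.25, 1e-6
        _, info, _ = score_info_residuals(d, ["x"], [beta], pooled=True)
        s_plus, _, _ = score_info_residuals(d, ["x"], [beta + h], pooled=True)
        s_minus, _, _ = score_info_residuals(d, ["x"], [beta - h], pooled=True)
        fd = -(s_plus[0] - s_minus[0]) / (2 * h)
        assert info[0, 0] == pytest.approx(fd, rel=1e-5)


class TestInvariants:
    def test_breslow_at_beta_zero_is_nelson_aalen(self, random_histories):
        d = to_counting_data(random_histories)
        t, inc = brute_breslow(d, ["x"], [0.0], stratum=None)
        # brute oracle with beta=0 is sum dN(t) / #at-risk
        ev = np.flatnonzero(d.status == 1)
        for tt, ii in zip(t, inc):
            n_risk = np.sum((d.start < tt) & (tt <= d.stop))
            n_ev = np.sum(d.stop[ev] == tt)
            assert ii == pytest.approx(n_ev / n_risk)

    def test_marginal_baseline_matches_brute(self, random_histories):
        d = to_counting_data(random_histories)
        fit = fit_marginal(d, ["x"])
        t, inc = fit.baseline[1]
        X = d.columns(["x"])
        for tt, ii in zip(t, inc):
            at_risk = (d.start < tt) & (tt <= d.stop)
            s0 = np.exp(X[at_risk, 0] * fit.beta[0]).sum()
            n_ev = np.sum((d.status == 1) & (d.stop == tt))
            assert ii == pytest.approx(n_ev / s0, abs=1e-12)

    def test_row_split_invariance(self, toy4_data):
        # split subject 2's censored row at 0.6: same risk exposure
        df = toy4_data.to_dataframe()
        row = df[(df.id == 2)].iloc[0]
        df = df[df.id != 2]
        parts = pd.DataFrame(
            {
                "id": [2, 2],
                "start": [0.0, 0.6],
                "stop": [0.6, 1.0],
                "status": [0, 0],
                "stratum": [1, 1],
                "x": [row.x, row.x],
                "z": [row.z, row.z],
            }
        )
        split = CountingData.from_dataframe(
            pd.concat([df, parts], ignore_index=True)
        )
        f_orig = fit_marginal(toy4_data, ["x"])
        f_split = fit_marginal(split, ["x"])
        assert f_split.beta[0] == pytest.approx(f_orig.beta[0], abs=1e-10)
        assert f_split.robust_se[0] == pytest.approx(f_orig.robust_se[0], abs=1e-10)

    def test_subject_permutation_invariance(self, random_histories):
        d = to_counting_data(random_histories)
        f1 = fit_marginal(d, ["x"])
        rng = np.random.default_rng(0)
        perm = rng.permutation(d.n_rows)
        d2 = CountingData(
            subject=d.subject[perm],
            start=d.start[perm],
            stop=d.stop[perm],
            status=d.status[perm],
            stratum=d.stratum[perm],
            covariates=d.covariates[perm],
            covariate_names=d.covariate_names,
        )
        f2 = fit_marginal(d2, ["x"])
        assert f2.beta[0] == pytest.approx(f1.beta[0], abs=1e-10)
        assert f2.naive_se[0] == pytest.approx(f1.naive_se[0], abs=1e-10)
        assert f2.robust_se[0] == pytest.approx(f1.robust_se[0], abs=1e-10)


class TestCrossCheckLifelines:
    def test_marginal_coefficient_matches_cox_time_varying(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(123)
        n = 300
        model = WeibullPoissonModel(
            lam=2.0 ** 0.8, kappa=1.25, eta=-0.3, zeta=0.4
        )
        x = (rng.random(n) < 0.5).astype(float)
        z = (rng.random(n) < 0.3).astype(float)
        c = np.ones(n)
        es, et = simulate_poisson_cohort(model, x, z, c, rng)
        data = counting_data_from_cohort(x, z, c, es, et)
        ours = fit_marginal(data, ["x", "z"])

        df = data.to_dataframe().drop(columns=["stratum"])
        ctv = lifelines.CoxTimeVaryingFitter()
        ctv.fit(df, id_col="id", event_col="status", start_col="start",
                stop_col="stop")
        theirs = ctv.params_
        assert ours.beta[0] == pytest.approx(theirs["x"], abs=1e-5)
        assert ours.beta[1] == pytest.approx(theirs["z"], abs=1e-5)


class TestWaldCI:
    def test_normal_quantile(self):
        from recurrates.fit import FitResult

        res = FitResult(
            beta=np.array([0.0]),
            naive_se=np.array([1.0]),
            robust_se=np.array([2.0]),
            score_norm=0.0,
            baseline={},
            n_events=1,
            n_subjects=1,
            converged=True,
            covariate_names=["x"],
        )
        ci = wald_ci(res, 0.95)
        assert ci["naive"][0] == pytest.approx([-1.959964, 1.959964], abs=1e-6)
        assert ci["robust"][0] == pytest.approx([-3.919928, 3.919928], abs=1e-6)

    def test_zero_se_degenerates(self):
        from recurrates.fit import FitResult

        res = FitResult(
            beta=np.array([0.5]),
            naive_se=np.array([0.0]),
            robust_se=np.array([0.0]),
            score_norm=0.0,
            baseline={},
            n_events=1,
            n_subjects=1,
            converged=True,
            covariate_names=["x"],
        )
        ci = wald_ci(res, 0.95)
        assert ci["naive"][0].tolist() == [0.5, 0.5]

    def test_invalid_level(self):
        from recurrates.fit import FitResult

        res = FitResult(
            beta=np.array([0.0]), naive_se=np.array([1.0]),
            robust_se=np.array([1.0]), score_norm=0.0, baseline={},
            n_events=1, n_subjects=1, converged=True, covariate_names=["x"],
        )
        with pytest.raises(ValueError):
            wald_ci(res, 1.5)


class TestCsvRoundTrip:
    def test_lossless(self, random_histories, tmp_path):
        d = to_counting_data(random_histories)
        path = tmp_path / "data.csv"
        d.write_csv(path)
        back = CountingData.read_csv(path)
        assert np.array_equal(back.start, d.start)
        assert np.array_equal(back.stop, d.stop)
        assert np.array_equal(back.status, d.status)
        assert np.array_equal(back.stratum, d.stratum)
        assert np.array_equal(back.covariates, d.covariates)
        header = path.read_text().splitlines()[0]
        assert header == "id,start,stop,status,stratum,x,z"
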