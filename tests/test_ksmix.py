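import numpy as np
import pandas as pd
import pytest

from wgdkit.ksmix import (
    KsDistribution,
    MixtureError,
    build_ks_distribution,
    fit_mixture_em,
    report_peaks,
    select_components,
)


def frame(ks_values, statuses=None):
    n = len(ks_values)
    return pd.DataFrame({
        "id_1": [f"a{i}" for i in range(n)],
        "id_2": [f"b{i}" for i in range(n)],
        "ks": ks_values,
        "status": statuses or ["ok"] * n,
    })


class TestBuildKsDistribution:
    def test_threshold_application(self):
        df = frame([0.5, 4.9, 5.2, np.nan], ["ok", "ok", "ok", "undefined"])
        dist = build_ks_distribution(df)
        assert sorted(dist.values) == [0.5, 4.9]
        assert dist.n_excluded == {"saturated": 0, "undefined": 1, "out_of_range": 1}

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no Ka/Ks"):
            build_ks_distribution(frame([]))

    def test_all_excluded_raises_with_advice(self):
        with pytest.raises(ValueError, match="truncation"):
            build_ks_distribution(frame([6.0, 7.0]))

    def test_matches_bruteforce_filter(self, rng):
        ks = rng.uniform(0, 8, size=200)
        statuses = rng.choice(["ok", "saturated", "undefined"], size=200,
                              p=[0.8, 0.1, 0.1]).tolist()
        dist = build_ks_distribution(frame(ks.tolist(), statuses))
        expected = sorted(
            k for k, s in zip(ks, statuses) if s == "ok" and 0.01 < k <= 5.0
        )
        assert sorted(dist.values) == pytest.approx(expected)

    def test_out_of_window_values_rejected_by_type(self):
        with pytest.raises(ValueError, match="truncation window"):
            KsDistribution(np.array([0.5, 7.0]))


class TestFitMixtureEM:
    def test_point_mass_single_component(self):
        dist = KsDistribution(np.full(50, 0.7))
        fit = fit_mixture_em(dist, k=1, seed=0)
        assert fit.mu[0] == pytest.approx(np.log(0.7))
        assert fit.medians[0] == pytest.approx(0.7)

    def test_single_component_equals_closed_form(self, rng):
        vals = rng.lognormal(-0.3, 0.4, size=400)
        vals = vals[(vals > 0.01) & (vals <= 5.0)]
        dist = KsDistribution(vals)
        fit = fit_mixture_em(dist, k=1, seed=3)
        x = np.log(vals)
        assert fit.mu[0] == pytest.approx(x.mean(), abs=1e-6)
        assert fit.sigma[0] == pytest.approx(x.std(), abs=1e-6)

    def test_two_planted_lognormal_peaks_recovered(self, rng):
        vals = np.concatenate([
            rng.lognormal(np.log(0.6), 0.25, size=2500),
            rng.lognormal(np.log(1.8), 0.25, size=2500),
        ])
        vals = vals[(vals > 0.01) & (vals <= 5.0)]
        fit = fit_mixture_em(KsDistribution(vals), k=2, seed=11)
        assert fit.medians[0] == pytest.approx(0.6, rel=0.10)
        assert fit.medians[1] == pytest.approx(1.8, rel=0.10)

    def test_loglik_trace_monotone(self, rng):
        vals = rng.lognormal(0.0, 0.5, size=300)
        vals = vals[(vals > 0.01) & (vals <= 5.0)]
        fit = fit_mixture_em(KsDistribution(vals), k=2, seed=5)
        trace = np.array(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-8).all()

    def test_deterministic_given_seed(self, rng):
        vals = rng.lognormal(0.0, 0.5, size=200)
        vals = vals[(vals > 0.01) & (vals <= 5.0)]
        dist = KsDistribution(vals)
        f1 = fit_mixture_em(dist, k=2, seed=9)
        f2 = fit_mixture_em(dist, k=2, seed=9)
        assert np.array_equal(f1.mu, f2.mu)
        assert f1.loglik == f2.loglik

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_mixture_em(KsDistribution(np.full(15, 1.0)), k=2, seed=0)

    def test_scale_equivariance(self, rng):
        vals = rng.lognormal(np.log(0.4), 0.3, size=500)
        vals = vals[(vals > 0.02) & (vals <= 2.0)]
        c = 2.0
        f1 = fit_mixture_em(KsDistribution(vals, 0.01, 5.0), k=2, seed=21)
        f2 = fit_mixture_em(KsDistribution(c * vals, 0.01, 10.0), k=2, seed=21)
        assert f2.mu == pytest.approx(f1.mu + np.log(c), abs=1e-3)
        assert f2.sigma == pytest.approx(f1.sigma, abs=1e-3)
        assert f2.weights == pytest.approx(f1.weights, abs=1e-3)


class TestSelectComponents:
    def test_unimodal_sample_selects_one(self, rng):
        vals = rng.lognormal(np.log(0.8), 0.3, size=600)
        vals = vals[(vals > 0.01) & (vals <= 5.0)]
        fit, table = select_components(KsDistribution(vals), seed=2)
        assert fit.k == 1

    def test_separated_bimodal_selects_two(self, rng):
        vals = np.concatenate([
            rng.lognormal(np.log(0.25), 0.2, size=400),
            rng.lognormal(np.log(2.5), 0.2, size=400),
        ])
        vals = vals[(vals > 0.01) & (vals <= 5.0)]
        fit, table = select_components(KsDistribution(vals), seed=2)
        assert fit.k == 2

    def test_small_samples_skip_large_k(self, rng):
        vals = rng.lognormal(0.0, 0.3, size=25)
        vals = vals[(vals > 0.01) & (vals <= 5.0)]
        fit, table = select_components(KsDistribution(vals), seed=1)
        assert set(table["k"]) <= {1, 2}

    def test_model_table_contains_all_fits(self, rng):
        vals = rng.lognormal(0.0, 0.4, size=300)
        vals = vals[(vals > 0.01) & (vals <= 5.0)]
        _, table = select_components(KsDistribution(vals), k_range=(1, 2, 3), seed=4)
        assert list(table["k"]) == [1, 2, 3]
        assert table["bic"].notna().all()


class TestReportPeaks:
    def _fit(self, weights, mu):
        from wgdkit.ksmix import KsMixtureFit

        w = np.asarray(weights, dtype=float)
        m = np.asarray(mu, dtype=float)
        return KsMixtureFit(len(w), w, m, np.full(len(w), 0.3), -1.0, 2.0,
                            100, True, 0)

    def test_both_components_reported(self):
        peaks = report_peaks(self._fit([0.6, 0.4], [np.log(0.6), np.log(1.8)]))
        assert len(peaks) == 2
        assert list(peaks["median_ks"]) == sorted(peaks["median_ks"])

    def test_minor_component_suppressed(self):
        peaks = report_peaks(self._fit([0.97, 0.03], [np.log(0.6), np.log(1.8)]))
        assert len(peaks) == 1
        assert peaks.loc[0, "median_ks"] == pytest.approx(0.6)

    def test_unconverged_fit_rejected(self):
        from wgdkit.ksmix import KsMixtureFit

        fit = KsMixtureFit(1, np.array([1.0]), np.array([0.0]),
                           np.array([0.3]), -1.0, 2.0, 100, False, 0)
        with pytest.raises(ValueError, match="converge"):
            report_peaks(fit)
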