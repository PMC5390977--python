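"""Repeated-measures agreement statistics: REML fit, 2SD, CP, ranking."""
import numpy as np
import pandas as pd
import pytest

from rrestim.agreement import (AgreementStats, _paired_arrays,
                               agreement_stats, compare_signals,
                               coverage_probability, fit_agreement_model,
                               moments_estimate, rank_methods,
                               two_sd_from_components)


def simulate_table(rng, n_subj=39, n_rep=40, bias=1.5, tau2=1.0,
                   s2_ref=0.5, s2_alg=2.0, omega2=1.0, nu2=4.0,
                   base=15.0):
    """Data drawn exactly from the crossed random-effects model."""
    rows = []
    for i in range(n_subj):
        mu = rng.normal(0, np.sqrt(nu2))
        c_ref = rng.normal(0, np.sqrt(tau2))
        c_alg = rng.normal(0, np.sqrt(tau2))
        for r in range(n_rep):
            a = rng.normal(0, np.sqrt(omega2))
            rows.append(("reference", i, r,
                         base + bias + mu + a + c_ref
                         + rng.normal(0, np.sqrt(s2_ref))))
            rows.append(("alg", i, r,
                         base + mu + a + c_alg
                         + rng.normal(0, np.sqrt(s2_alg))))
    return pd.DataFrame(rows,
                        columns=["method", "subject", "replicate",
                                 "value"])


class TestTwoSD:
    def test_closed_form_arithmetic(self):
        assert two_sd_from_components(0.0, 1.0, 3.0) == pytest.approx(4.0)
        assert two_sd_from_components(2.0, 0.0, 0.0) == pytest.approx(4.0)

    def test_coverage_probability_empirical_cdf(self):
        assert coverage_probability(np.array([1, 3, 1, 5]), 2.0) \
            == pytest.approx(50.0)

    def test_cp_monotone_in_delta(self):
        rng = np.random.default_rng(0)
        err = np.abs(rng.normal(size=200))
        cps = [coverage_probability(err, d)
               for d in np.linspace(0.1, 3, 15)]
        assert all(a <= b for a, b in zip(cps[:-1], cps[1:]))


class TestModelFit:
    def test_parameter_recovery_single_fit(self):
        rng = np.random.default_rng(101)
        df = simulate_table(rng)
        fit = fit_agreement_model(df, "reference", "alg")
        assert fit.converged
        stats = agreement_stats(fit, df)
        truth = two_sd_from_components(1.0, 0.5, 2.0)
        assert stats.bias == pytest.approx(1.5, abs=0.5)
        assert stats.two_sd == pytest.approx(truth, rel=0.15)

    def test_reml_matches_moments_oracle(self):
        rng = np.random.default_rng(11)
        df = simulate_table(rng)
        fit = fit_agreement_model(df, "reference", "alg")
        mom = moments_estimate(_paired_arrays(df, "reference", "alg"))
        assert fit.sigma2["reference"] == pytest.approx(
            mom["sigma2_ref"], rel=0.10)
        assert fit.sigma2["alg"] == pytest.approx(mom["sigma2_alg"],
                                                  rel=0.10)
        assert 2 * fit.tau2 + sum(fit.sigma2.values()) == pytest.approx(
            2 * mom["tau2"] + mom["sigma2_ref"] + mom["sigma2_alg"],
            rel=0.10)

    def test_symmetric_generator_gives_equal_residuals(self):
        rng = np.random.default_rng(21)
        df = simulate_table(rng, tau2=1e-12, s2_ref=1.0, s2_alg=1.0,
                            n_subj=40, n_rep=40)
        fit = fit_agreement_model(df, "reference", "alg")
        assert fit.converged
        assert fit.sigma2["reference"] == pytest.approx(
            fit.sigma2["alg"], rel=0.10)

    def test_constant_shift_moves_bias_not_two_sd(self):
        rng = np.random.default_rng(31)
        df = simulate_table(rng, n_subj=15, n_rep=20)
        fit0 = fit_agreement_model(df, "reference", "alg")
        shifted = df.copy()
        alg_rows = shifted["method"] == "alg"
        shifted.loc[alg_rows, "value"] += 5.0
        fit1 = fit_agreement_model(shifted, "reference", "alg")
        s0 = agreement_stats(fit0, df)
        s1 = agreement_stats(fit1, shifted)
        assert s1.bias == pytest.approx(s0.bias - 5.0, abs=1e-3)
        assert s1.two_sd == pytest.approx(s0.two_sd, rel=1e-3)

    def test_degenerate_tables_do_not_converge(self):
        one_subj = simulate_table(np.random.default_rng(0), n_subj=1)
        assert not fit_agreement_model(one_subj, "reference",
                                       "alg").converged
        const = simulate_table(np.random.default_rng(0), n_subj=6,
                               n_rep=5)
        const["value"] = 17.0
        assert not fit_agreement_model(const, "reference",
                                       "alg").converged

    def test_zero_noise_never_inflates_two_sd(self):
        df = simulate_table(np.random.default_rng(0), n_subj=8, n_rep=10)
        ref = df[df.method == "reference"].copy()
        alg = ref.copy()
        alg["method"] = "alg"
        identical = pd.concat([ref, alg], ignore_index=True)
        fit = fit_agreement_model(identical, "reference", "alg")
        if fit.converged:
            stats = agreement_stats(fit, identical)
            assert stats.bias == pytest.approx(0.0, abs=1e-4)
            assert stats.two_sd < 1e-2


class TestRanking:
    def _stat(self, two_sd, bias):
        return AgreementStats(bias=bias, two_sd=two_sd,
                              loa=(bias - two_sd, bias + two_sd),
                              cp=np.nan, delta=2.0, coverage=np.nan)

    def test_sort_by_two_sd_then_absolute_bias(self):
        stats = [self._stat(5.2, 1.4), self._stat(4.7, 0.0),
                 self._stat(5.2, -2.0)]
        assert rank_methods(stats) == [1, 0, 2]

    def test_rounding_before_sorting(self):
        stats = [self._stat(5.24, 3.0), self._stat(5.16, 1.0)]
        assert rank_methods(stats) == [1, 0]

    def test_ties_preserve_input_order(self):
        stats = [self._stat(5.0, 1.0), self._stat(5.0, 1.0)]
        assert rank_methods(stats) == [0, 1]

    def test_unavailable_sorts_last(self):
        stats = [AgreementStats(np.nan, np.nan, (np.nan, np.nan), np.nan,
                                2.0, np.nan, available=False),
                 self._stat(6.0, 0.0)]
        assert rank_methods(stats) == [1, 0]


class TestSignalComparison:
    def test_identical_pairs(self):
        pairs = [(5.0, 5.0)] * 8
        _, p, med = compare_signals(pairs)
        assert p == pytest.approx(1.0)
        assert med == pytest.approx(0.0)

    def test_all_negative_exact_p(self):
        pairs = [(1, 2), (2, 4), (3, 6), (4, 8), (5, 10), (6, 12)]
        _, p, med = compare_signals(pairs)
        assert p == pytest.approx(2 / 64)
        assert med < 0

    def test_zero_differences_dropped(self):
        pairs = [(1, 2), (2, 4), (3, 6), (4, 8), (5, 10), (6, 12),
                 (7, 7)]
        _, p, _ = compare_signals(pairs)
        assert p == pytest.approx(2 / 64)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            compare_signals([(1.0, 2.0)] * 5)
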