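"""Limits of agreement with repeated measures.

Agreement between an RR method and the reference is modelled with a crossed
random-effects model::

    y_mir = alpha_m + mu_i + a_ir + c_mi + e_mir
    mu_i ~ N(0, nu^2)      subject effect
    a_ir ~ N(0, omega^2)   shared replicate (window) effect within subject
    c_mi ~ N(0, tau^2)     method-by-subject interaction
    e_mir ~ N(0, sigma_m^2)  method-specific residual

where ``m`` indexes the method, ``i`` the subject and ``r`` the replicate.
The method bias is ``alpha_ref - alpha_alg`` and the half-width of the 95%
limits of agreement is::

    2SD = 2 * sqrt(2*tau^2 + sigma_ref^2 + sigma_alg^2)

(the subject and replicate effects cancel in the paired difference).  The
model is fit by restricted maximum likelihood with the fixed effects
profiled out; variance parameters are optimised on the log scale starting
from closed-form method-of-moments values.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_LOG_FLOOR = np.log(1e-8)


@dataclass
class RandomEffectsFit:
    alpha: dict  # per-method fixed bias
    nu2: float  # between-subject variance
    omega2: float  # replicate-within-subject variance
    tau2: float  # method-by-subject interaction variance
    sigma2: dict  # per-method residual variance
    converged: bool
    ref_method: str
    alg_method: str
    n_subjects: int = 0
    loglik: float = np.nan


@dataclass
class AgreementStats:
    bias: float  # alpha_ref - alpha_alg, bpm
    two_sd: float  # bpm
    loa: tuple  # (bias - 2SD, bias + 2SD)
    cp: float  # coverage probability within delta, percent
    delta: float
    coverage: float  # percent of quality-passed windows with an output
    available: bool = True
    extra: dict = field(default_factory=dict)


def _paired_arrays(table: pd.DataFrame, ref_method: str,
                   alg_method: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-subject (ref, alg) replicate vectors, paired on replicate id."""
    out = []
    for _, g in table.groupby("subject"):
        wide = g.pivot_table(index="replicate", columns="method",
                             values="value")
        if ref_method not in wide or alg_method not in wide:
            continue
        wide = wide[[ref_method, alg_method]].dropna()
        if len(wide) >= 2:
            out.append((wide[ref_method].to_numpy(),
                        wide[alg_method].to_numpy()))
    return out


def moments_estimate(pairs: list[tuple[np.ndarray, np.ndarray]]) -> dict:
    """Closed-form method-of-moments variance components (balanced logic).

    Independent of the REML path; also used as its starting point. Within
    each (method, subject) cell the sample variance estimates
    ``omega^2 + sigma_m^2`` and the cross-method covariance of the centred
    replicates estimates ``omega^2``; a one-way ANOVA on the paired
    differences separates ``2*tau^2`` from ``sigma_ref^2 + sigma_alg^2``.
    """
    d_means, d_all, ns = [], [], []
    s2_ref, s2_alg, covs = [], [], []
    for ref, alg in pairs:
        d = ref - alg
        d_means.append(d.mean())
        d_all.append(d)
        ns.append(d.size)
        rc = ref - ref.mean()
        ac = alg - alg.mean()
        s2_ref.append(rc @ rc / (rc.size - 1))
        s2_alg.append(ac @ ac / (ac.size - 1))
        covs.append(rc @ ac / (rc.size - 1))
    ns = np.asarray(ns, dtype=float)
    nbar = ns.mean()
    ms_w = float(np.mean([np.var(d, ddof=1) for d in d_all]))
    ms_b = float(np.var(d_means, ddof=1) * nbar) if len(d_means) > 1 \
        else ms_w
    tau2 = max((ms_b - ms_w) / (2.0 * nbar), 0.0)
    omega2 = max(float(np.mean(covs)), 0.0)
    sigma2_ref = max(float(np.mean(s2_ref)) - omega2, 1e-10)
    sigma2_alg = max(float(np.mean(s2_alg)) - omega2, 1e-10)
    subj_means = [np.concatenate([r, a]).mean() for r, a in pairs]
    nu2 = max(float(np.var(subj_means, ddof=1)) if len(pairs) > 1 else 0.0,
              1e-10)
    alpha_ref = float(np.mean([r.mean() for r, _ in pairs]))
    alpha_alg = float(np.mean([a.mean() for _, a in pairs]))
    return {"nu2": nu2, "omega2": max(omega2, 1e-10),
            "tau2": max(tau2, 1e-10),
            "sigma2_ref": sigma2_ref, "sigma2_alg": sigma2_alg,
            "alpha_ref": alpha_ref, "alpha_alg": alpha_alg}


def _neg_reml(log_theta: np.ndarray,
              groups: dict) -> float:
    """-2 x restricted log-likelihood with fixed effects profiled out.

    ``groups`` maps replicate count R -> stacked data matrix Y of shape
    (2R, n_subjects_with_R); subjects sharing R share one block covariance.
    """
    nu2, omega2, tau2, s2r, s2a = np.exp(log_theta)
    logdet_total = 0.0
    xtvx = np.zeros((2, 2))
    xtvy = np.zeros(2)
    ytvy = 0.0
    for r_count, y_mat in groups.items():
        r = r_count
        jr = np.ones((r, r))
        ir = np.eye(r)
        # block order: [ref replicates, alg replicates]
        sigma = np.empty((2 * r, 2 * r))
        sigma[:r, :r] = nu2 + tau2 * jr + omega2 * ir + s2r * ir
        sigma[r:, r:] = nu2 + tau2 * jr + omega2 * ir + s2a * ir
        sigma[:r, r:] = nu2 + omega2 * ir
        sigma[r:, :r] = nu2 + omega2 * ir
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return np.inf
        n_g = y_mat.shape[1]
        logdet_total += 2.0 * n_g * float(np.sum(np.log(np.diag(chol))))
        x = np.zeros((2 * r, 2))
        x[:r, 0] = 1.0  # alpha_ref
        x[r:, 1] = 1.0  # alpha_alg
        rhs = np.concatenate([x, y_mat], axis=1)
        sol = np.linalg.solve(chol, rhs)  # chol^-1 [X Y]
        sx, sy = sol[:, :2], sol[:, 2:]
        xtvx += n_g * (sx.T @ sx)
        xtvy += (sx.T @ sy).sum(axis=1)
        ytvy += float(np.sum(sy * sy))
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - float(xtvy @ beta)
    return logdet_total + logdet_xtvx + quad


def fit_agreement_model(table: pd.DataFrame,
                        ref_method: str = "reference",
                        alg_method: str | None = None
                        ) -> RandomEffectsFit:
    """REML fit of the crossed random-effects agreement model.

    ``table`` has columns ``method``, ``subject``, ``replicate``, ``value``
    with exactly two methods. Non-convergence (optimiser failure, non-finite
    estimates, degenerate data) is a reportable state, not an exception.
    """
    methods = sorted(table["method"].unique())
    if alg_method is None:
        others = [m for m in methods if m != ref_method]
        if len(others) != 1:
            raise ValueError("table must contain the reference and exactly "
                             "one algorithm method")
        alg_method = others[0]

    def _failed() -> RandomEffectsFit:
        return RandomEffectsFit({}, np.nan, np.nan, np.nan, {}, False,
                                ref_method, alg_method)

    pairs = _paired_arrays(table, ref_method, alg_method)
    if len(pairs) < 2:
        return _failed()
    values = np.concatenate([np.concatenate([r, a]) for r, a in pairs])
    if np.ptp(values) == 0:
        return _failed()

    init = moments_estimate(pairs)
    groups: dict[int, np.ndarray] = {}
    for ref, alg in pairs:
        groups.setdefault(ref.size, []).append(np.concatenate([ref, alg]))
    groups = {r: np.column_stack(v) for r, v in groups.items()}

    x0 = np.log(np.maximum(
        [init["nu2"], init["omega2"], init["tau2"],
         init["sigma2_ref"], init["sigma2_alg"]], 1e-8))
    res = optimize.minimize(_neg_reml, x0, args=(groups,),
                            method="L-BFGS-B",
                            bounds=[(_LOG_FLOOR, 20.0)] * 5)
    if not res.success or not np.isfinite(res.fun):
        res2 = optimize.minimize(_neg_reml, x0, args=(groups,),
                                 method="Nelder-Mead",
                                 options={"maxiter": 4000, "xatol": 1e-6,
                                          "fatol": 1e-8})
        if res2.fun <= res.fun or not np.isfinite(res.fun):
            res = res2
    if not np.isfinite(res.fun):
        return _failed()
    nu2, omega2, tau2, s2r, s2a = np.exp(res.x)

    # GLS fixed effects at the optimum
    xtvx = np.zeros((2, 2))
    xtvy = np.zeros(2)
    for r, y_mat in groups.items():
        jr = np.ones((r, r))
        ir = np.eye(r)
        sigma = np.empty((2 * r, 2 * r))
        sigma[:r, :r] = nu2 + tau2 * jr + (omega2 + s2r) * ir
        sigma[r:, r:] = nu2 + tau2 * jr + (omega2 + s2a) * ir
        sigma[:r, r:] = sigma[r:, :r] = nu2 + omega2 * ir
        x = np.zeros((2 * r, 2))
        x[:r, 0] = 1.0
        x[r:, 1] = 1.0
        vinv_x = np.linalg.solve(sigma, x)
        xtvx += x.T @ vinv_x * y_mat.shape[1]
        xtvy += vinv_x.T @ y_mat.sum(axis=1)
    alpha = np.linalg.solve(xtvx, xtvy)

    converged = bool(res.success or
                     (np.isfinite(res.fun) and np.all(np.isfinite(res.x))))
    # degenerate boundary fits (variances pinned at the floor everywhere)
    if not np.all(np.isfinite(alpha)):
        converged = False
    return RandomEffectsFit(
        alpha={ref_method: float(alpha[0]), alg_method: float(alpha[1])},
        nu2=float(nu2), omega2=float(omega2), tau2=float(tau2),
        sigma2={ref_method: float(s2r), alg_method: float(s2a)},
        converged=converged, ref_method=ref_method, alg_method=alg_method,
        n_subjects=len(pairs), loglik=-0.5 * float(res.fun))


def two_sd_from_components(tau2: float, sigma2_ref: float,
                           sigma2_alg: float) -> float:
    """Half-width of the 95% limits of agreement from the variance
    components: ``2*sqrt(2*tau^2 + sigma_ref^2 + sigma_alg^2)``."""
    return 2.0 * float(np.sqrt(2.0 * tau2 + sigma2_ref + sigma2_alg))


def coverage_probability(abs_errors: np.ndarray, delta: float = 2.0
                         ) -> float:
    """Empirical CDF of the absolute error at ``delta``, as a percent."""
    abs_errors = np.asarray(abs_errors, dtype=float)
    if abs_errors.size == 0:
        return np.nan
    return 100.0 * float(np.mean(abs_errors <= delta))


def agreement_stats(fit: RandomEffectsFit, table: pd.DataFrame,
                    delta: float = 2.0,
                    coverage: float = np.nan) -> AgreementStats:
    """Bias, 2SD, LOA and CP_delta for one algorithm-signal combination."""
    if not fit.converged:
        return AgreementStats(np.nan, np.nan, (np.nan, np.nan), np.nan,
                              delta, coverage, available=False)
    bias = fit.alpha[fit.ref_method] - fit.alpha[fit.alg_method]
    two_sd = two_sd_from_components(fit.tau2, fit.sigma2[fit.ref_method],
                                    fit.sigma2[fit.alg_method])
    pairs = _paired_arrays(table, fit.ref_method, fit.alg_method)
    abs_err = np.concatenate([np.abs(a - r) for r, a in pairs]) \
        if pairs else np.empty(0)
    cp = coverage_probability(abs_err, delta)
    return AgreementStats(bias=float(bias), two_sd=float(two_sd),
                          loa=(bias - two_sd, bias + two_sd), cp=cp,
                          delta=delta, coverage=coverage)


def rank_methods(stats_list: list[AgreementStats]) -> list[int]:
    """Indices ordering methods by (2SD, |bias|), both rounded to one
    decimal place; ties preserve input order; unavailable stats sort last."""
    def key(i: int):
        s = stats_list[i]
        if not s.available or not np.isfinite(s.two_sd):
            return (np.inf, np.inf, i)
        return (round(s.two_sd, 1), round(abs(s.bias), 1), i)
    return sorted(range(len(stats_list)), key=key)


def compare_signals(paired_two_sd: list[tuple[float, float]]
                    ) -> tuple[float, float, float]:
    """Paired Wilcoxon signed-rank comparison of ECG vs PPG precision.

    Zero differences are dropped before ranking; the exact null
    distribution is used for n <= 25 remaining pairs, the normal
    approximation above. Returns (statistic, p_value, median_difference).
    """
    pairs = [(e, p) for e, p in paired_two_sd
             if np.isfinite(e) and np.isfinite(p)]
    if len(pairs) < 6:
        raise ValueError("need at least 6 complete pairs")
    ecg = np.array([e for e, _ in pairs])
    ppg = np.array([p for _, p in pairs])
    diffs = ecg - ppg
    median_diff = float(np.median(diffs))
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return np.nan, 1.0, median_diff
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(nz, zero_method="wilcox", method=method,
                         alternative="two-sided")
    return float(res.statistic), float(res.pvalue), median_diff
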