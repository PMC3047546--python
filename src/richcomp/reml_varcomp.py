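"""REML estimation of the crossed-random-effects model.

Model: y ~ N(X beta, sum_m sigma2_m Z_m Z_m' + sigma2 I) with fixed
intercept and overall log2-richness slope, and up to five random batches
(site, block, composition, per-site slope deviations, site x
composition).  The covariance algebra is dense -- intended for datasets
of at most a few thousand plots -- and the objective is maximized by
quasi-Newton iteration on log variances with an analytic gradient.
"""
from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .design import BATCHES, ModelFrame
from .study_data import PlotRecord

DEFAULT_RANDOM_TERMS = BATCHES  # all five batches; residual is implicit

_LOGVAR_FLOOR = 1e-10


class NotConvergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class OptimizerSettings:
    n_starts: int = 3
    maxiter: int = 500
    gtol: float = 1e-6


@dataclass
class RemlFit:
    terms: tuple[str, ...]
    beta: np.ndarray  # (intercept, slope)
    beta_se: np.ndarray
    variances: dict  # term -> sigma^2 (includes "residual")
    sds: dict
    percent_shares: dict  # variance-scale shares over terms + residual
    blups: dict  # term -> level-effect predictions
    level_names: dict  # term -> level labels, aligned with blups
    reml_loglik: float
    converged: bool
    x_center: float
    n: int


def _build(records: Sequence[PlotRecord], terms: Sequence[str]):
    frame = ModelFrame.from_records(records)
    # constant richness (degenerate toy designs): intercept-only fixed part
    if np.ptp(frame.x) > 0:
        X = np.column_stack([np.ones(frame.n), frame.x])
    else:
        X = np.ones((frame.n, 1))
    Zs = [frame.z_matrix(t) for t in terms]
    Gs = [Z @ Z.T for Z in Zs]
    return frame, X, Zs, Gs


def _neg_loglik_and_grad(theta, y, X, Gs, reml):
    """Negative (restricted) log-likelihood and gradient on log-variances.

    theta = log variances, batches first then residual.
    """
    n = len(y)
    sig2 = np.exp(theta)
    V = sig2[-1] * np.eye(n)
    for s2, G in zip(sig2[:-1], Gs):
        V += s2 * G
    cf = linalg.cho_factor(V, lower=True, check_finite=False)
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vinv = linalg.cho_solve(cf, np.eye(n), check_finite=False)
    XtVi = X.T @ Vinv
    A = XtVi @ X
    beta = np.linalg.solve(A, XtVi @ y)
    r = y - X @ beta
    u = Vinv @ r
    quad = float(r @ u)
    ll = -0.5 * (logdetV + quad)
    if reml:
        ll -= 0.5 * float(np.linalg.slogdet(A)[1])
        P = Vinv - XtVi.T @ np.linalg.solve(A, XtVi)
    else:
        P = Vinv
    grads = np.empty(len(theta))
    for m, G in enumerate(Gs):
        grads[m] = -0.5 * (np.einsum("ij,ij->", P, G) - u @ G @ u)
    grads[-1] = -0.5 * (np.trace(P) - u @ u)
    # chain rule onto the log scale
    return -ll, -(grads * sig2), beta, A, Vinv, u


def _objective(theta, y, X, Gs, reml=True):
    nll, ngrad, *_ = _neg_loglik_and_grad(theta, y, X, Gs, reml)
    return nll, ngrad


def _optimize(y, X, Gs, settings: OptimizerSettings, reml=True):
    var_y = float(np.var(y, ddof=1))
    k = len(Gs)
    starts = [
        np.full(k + 1, var_y / (k + 1)),
        np.concatenate([np.full(k, var_y / 10.0), [var_y]]),
        np.concatenate([np.full(k, var_y), [var_y / 10.0]]),
    ][: max(1, settings.n_starts)]
    lo = np.log(_LOGVAR_FLOOR * max(var_y, 1.0))
    hi = np.log(1e4 * max(var_y, 1.0))
    best = None
    for start in starts:
        res = optimize.minimize(
            _objective,
            np.log(np.clip(start, np.exp(lo), np.exp(hi))),
            args=(y, X, Gs, reml),
            jac=True,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * (k + 1),
            options={"maxiter": settings.maxiter, "gtol": settings.gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def reml_fit(
    records: Sequence[PlotRecord],
    terms: Sequence[str] = DEFAULT_RANDOM_TERMS,
    settings: OptimizerSettings = OptimizerSettings(),
    include_residual_in_shares: bool = True,
) -> RemlFit:
    """Fit the mixed model by REML and return variance components, fixed
    effects and BLUPs.

    A stalled optimizer yields ``converged=False`` rather than an
    exception.  Percent shares follow the variance-scale convention over
    the random terms (residual included by default).
    """
    terms = tuple(terms)
    frame, X, Zs, Gs = _build(records, terms)
    for t, Z in zip(terms, Zs):
        if Z.shape[1] < 2:
            raise ValueError(f"batch {t!r} has fewer than 2 levels")
    res = _optimize(frame.y, X, Gs, settings, reml=True)
    nll, _, beta, A, Vinv, u = _neg_loglik_and_grad(res.x, frame.y, X, Gs, reml=True)
    sig2 = np.exp(res.x)
    Ainv = np.linalg.inv(A)
    beta_se = np.sqrt(np.diag(Ainv))

    variances = {t: float(s2) for t, s2 in zip(terms, sig2[:-1])}
    variances["residual"] = float(sig2[-1])
    sds = {t: float(np.sqrt(v)) for t, v in variances.items()}
    share_terms = list(terms) + (["residual"] if include_residual_in_shares else [])
    total = sum(variances[t] for t in share_terms)
    percent_shares = {t: 100.0 * variances[t] / total for t in share_terms}

    blups = {
        t: s2 * (Z.T @ u) for t, s2, Z in zip(terms, sig2[:-1], Zs)
    }
    level_names = {
        t: {
            "experiment": frame.site_levels,
            "block": frame.block_levels,
            "composition": frame.comp_levels,
            "experiment:richness": frame.site_levels,
            "experiment:composition": frame.pair_levels,
        }[t]
        for t in terms
    }
    return RemlFit(
        terms=terms,
        beta=beta,
        beta_se=beta_se,
        variances=variances,
        sds=sds,
        percent_shares=percent_shares,
        blups={t: np.asarray(v) for t, v in blups.items()},
        level_names=level_names,
        reml_loglik=float(-nll),
        converged=bool(res.success),
        x_center=frame.x_center,
        n=frame.n,
    )


def reml_loglik_at(
    records: Sequence[PlotRecord],
    terms: Sequence[str],
    variances: Sequence[float],
) -> float:
    """REML log-likelihood at a given parameter point (batches then residual)."""
    frame, X, _, Gs = _build(records, tuple(terms))
    theta = np.log(np.clip(np.asarray(variances, dtype=float), _LOGVAR_FLOOR, None))
    nll, _, *_ = _neg_loglik_and_grad(theta, frame.y, X, Gs, reml=True)
    return -nll


@dataclass(frozen=True)
class FixedEffectAnova:
    source: str
    df: int
    ss: float
    ms: float
    f: float
    note: str = "Wald-type: F = (slope/SE)^2; SS = MS = F x residual variance"


def fixed_effect_anova(fit: RemlFit) -> FixedEffectAnova:
    """Wald-type 1-DF F test for the fixed richness slope.

    No P value is emitted; the SS/MS accounting scales the F by the
    residual variance so the row reads like a classical ANOVA line.
    """
    if not fit.converged:
        raise NotConvergedError("refusing to test a non-converged fit")
    if len(fit.beta) < 2:
        raise ValueError("fit has no richness slope (constant richness)")
    f = float((fit.beta[1] / fit.beta_se[1]) ** 2)
    ss = f * fit.variances["residual"]
    return FixedEffectAnova(source="richness", df=1, ss=ss, ms=ss, f=f)


def ml_deviance(
    records: Sequence[PlotRecord],
    terms: Sequence[str],
    settings: OptimizerSettings = OptimizerSettings(),
) -> float:
    """-2 x maximized ML log-likelihood (constants included)."""
    frame, X, _, Gs = _build(records, tuple(terms))
    res = _optimize(frame.y, X, Gs, settings, reml=False)
    n = frame.n
    return float(2.0 * res.fun + n * np.log(2.0 * np.pi))


@dataclass(frozen=True)
class LrtResult:
    dropped: str
    delta_deviance: float
    p_chisq1: float
    p_halfmix: float


def lrt_random_term(
    records: Sequence[PlotRecord],
    full_terms: Sequence[str],
    dropped: str,
    settings: OptimizerSettings = OptimizerSettings(),
) -> LrtResult:
    """Likelihood-ratio test for one random batch, by ML on both models.

    Because the null (variance = 0) sits on the boundary, both the naive
    chi-square(1) P and the 50:50 mixture chi-square(0):chi-square(1) P
    are reported.
    """
    full_terms = tuple(full_terms)
    if dropped not in full_terms:
        raise KeyError(f"term {dropped!r} not in the full model")
    reduced = tuple(t for t in full_terms if t != dropped)
    dev_full = ml_deviance(records, full_terms, settings)
    dev_reduced = ml_deviance(records, reduced, settings)
    delta = max(dev_reduced - dev_full, 0.0)
    # optimizer-tolerance deviances count as the boundary case delta = 0
    at_boundary = delta <= 1e-6
    p1 = 1.0 if at_boundary else float(stats.chi2.sf(delta, 1))
    p_mix = 1.0 if at_boundary else float(0.5 * stats.chi2.sf(delta, 1))
    return LrtResult(dropped=dropped, delta_deviance=delta, p_chisq1=p1, p_halfmix=p_mix)


def blup_slopes(fit: RemlFit) -> pd.Series:
    """Per-site predicted slope: overall slope + BLUP slope deviation."""
    if "experiment:richness" not in fit.terms:
        raise KeyError("fit does not include the experiment:richness batch")
    dev = fit.blups["experiment:richness"]
    sites = fit.level_names["experiment:richness"]
    return pd.Series(fit.beta[1] + dev, index=sites, name="blup_slope")


def varcomp_table(fit: RemlFit) -> pd.DataFrame:
    """Variance-component table: variance, SD and percent share per term."""
    rows = []
    for term in list(fit.terms) + ["residual"]:
        rows.append(
            {
                "source": term,
                "variance": fit.variances[term],
                "sd": fit.sds[term],
                "percent": fit.percent_shares.get(term, np.nan),
            }
        )
    return pd.DataFrame(rows)
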