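"""Gibbs sampler for the hierarchical model with finite-population SDs.

The model places independent zero-mean normal priors on five effect
batches (site, block, composition, per-site slope deviations, site x
composition), a diffuse normal prior on the grand mean and overall
log2-richness slope, and -- by default -- uniform priors on every batch
SD and the residual SD.  Every full conditional is sampled exactly: the
location parameters and effect blocks from Gaussians, and under the
uniform-SD prior each variance from its truncated scaled-inverse
chi-square conditional, keeping the scheme pure Gibbs.

For every retained draw the sampler also records the finite-population
SD of each source: the SD over a batch's realized level effects
(categorical sources) or over the plot-level centered slope
contributions (richness and site x richness), plus the SD of the
realized residuals.
"""
from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .design import BATCHES, SOURCES, ModelFrame
from .study_data import PlotRecord


class SettingsError(ValueError):
    pass


@dataclass(frozen=True)
class MCMCSettings:
    n_chains: int = 3
    n_iter: int = 100_000
    burn_in: int = 5_000
    thin: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise SettingsError("need >= 2 chains")
        if not 0 <= self.burn_in < self.n_iter:
            raise SettingsError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise SettingsError("thin must be >= 1")
        if self.retained_per_chain < 50:
            raise SettingsError(
                f"settings retain only {self.retained_per_chain} draws per chain (< 50)"
            )

    @property
    def retained_per_chain(self) -> int:
        """Draws kept per chain: every thin-th iteration after burn-in."""
        return (self.n_iter - self.burn_in) // self.thin


@dataclass(frozen=True)
class PriorSpec:
    """Vague priors: uniform(0, sd_upper) on SDs (default upper bound
    10 x sample SD of the response) and normal(0, loc_scale^2) on the
    grand mean and overall slope.  ``family="inv_gamma"`` switches the
    variances to inverse-gamma(0.001, 0.001) for sensitivity checks."""

    sd_upper: float | None = None
    loc_scale: float = 1e6
    family: str = "uniform_sd"

    def __post_init__(self) -> None:
        if self.sd_upper is not None and self.sd_upper <= 0:
            raise SettingsError("sd_upper must be > 0")
        if self.loc_scale <= 0:
            raise SettingsError("loc_scale must be > 0")
        if self.family not in ("uniform_sd", "inv_gamma"):
            raise SettingsError(f"unknown prior family {self.family!r}")


@dataclass
class PosteriorDraws:
    """Retained MCMC output, shaped (chains, draws[, levels])."""

    settings: MCMCSettings
    priors: PriorSpec
    beta0: np.ndarray
    slope: np.ndarray
    effects: dict  # batch -> (chains, draws, levels)
    sigma: dict  # batch + "residual" -> super-population SD draws
    s: dict  # source (incl richness/residual) -> finite-population SD draws
    x_sd: float
    level_names: dict

    def monitored(self) -> dict:
        """Scalar chains for convergence monitoring."""
        out = {"beta0": self.beta0, "slope": self.slope}
        for name, arr in self.sigma.items():
            out[f"sigma[{name}]"] = arr
        for name, arr in self.s.items():
            out[f"s[{name}]"] = arr
        return out


def finite_pop_sd(values: np.ndarray, kind: str = "categorical") -> float:
    """Finite-population SD of realized effects.

    ``categorical``: SD over a batch's level effects (denominator J-1).
    ``continuous``: SD over plot-level centered contributions, e.g. the
    slope times centered log2 richness (denominator n-1).  Both center at
    the mean, so the result is translation invariant.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("finite-population SD undefined for fewer than 2 values")
    if kind not in ("categorical", "continuous"):
        raise ValueError(f"unknown kind {kind!r}")
    return float(np.std(values, ddof=1))


def _sample_level_effects(rng, partial, idx, coef, nlev, s2e, s2m):
    """Draw a whole effect batch from its Gaussian full conditional.

    ``partial`` is the residual with this batch's contribution removed;
    ``coef`` the per-row covariate (ones for indicator batches).
    """
    cw = np.bincount(idx, weights=coef * coef, minlength=nlev)
    sw = np.bincount(idx, weights=coef * partial, minlength=nlev)
    prec = cw / s2e + 1.0 / s2m
    mean = sw / s2e / prec
    return mean + rng.standard_normal(nlev) / np.sqrt(prec)


def _sample_comp_pair_joint(rng, partial, comp_idx, pair_idx, pair_comp, n_pair_obs,
                            n_comp, n_pair, s2e, s2c, s2g):
    """Joint draw of the composition and site-x-composition batches.

    Compositions occurring at a single site identify only the sum of the
    two effects, so alternating single-batch updates random-walk the
    split and mix very slowly.  Sampling the composition effects with
    the interaction integrated out (each pair mean then carries variance
    s2g + s2e/n_p), followed by the interaction conditionally, is an
    exact draw from the joint Gaussian full conditional and removes the
    random walk.
    """
    pair_sum = np.bincount(pair_idx, weights=partial, minlength=n_pair)
    pair_mean = pair_sum / n_pair_obs
    w = 1.0 / (s2g + s2e / n_pair_obs)  # precision of each pair mean about c
    prec_c = 1.0 / s2c + np.bincount(pair_comp, weights=w, minlength=n_comp)
    mean_c = np.bincount(pair_comp, weights=w * pair_mean, minlength=n_comp) / prec_c
    c = mean_c + rng.standard_normal(n_comp) / np.sqrt(prec_c)
    prec_g = n_pair_obs / s2e + 1.0 / s2g
    mean_g = (pair_sum - n_pair_obs * c[pair_comp]) / s2e / prec_g
    g = mean_g + rng.standard_normal(n_pair) / np.sqrt(prec_g)
    return c, g


def _sample_variance(rng, ssq, nterms, upper_sq, family):
    """Draw a variance from its full conditional.

    uniform_sd: ssq/sigma^2 ~ chi-square(nterms - 1) truncated to
    sigma < upper (the flat prior on sigma contributes (sigma^2)^(-1/2)).
    Sampled by rejection from the untruncated chi-square -- the wide
    default prior rarely truncates -- with an exact inverse-CDF fallback.
    inv_gamma: conjugate inverse-gamma(0.001 + n/2, 0.001 + ssq/2).
    """
    if family == "inv_gamma":
        shape = 0.001 + 0.5 * nterms
        rate = 0.001 + 0.5 * ssq
        return rate / rng.gamma(shape, 1.0)
    df = nterms - 1
    cut = ssq / upper_sq  # need chi-square draw above this
    for _ in range(8):
        draw = rng.chisquare(df)
        if draw > cut:
            return ssq / draw
    lo = special.chdtr(df, cut)
    q = min(max(lo + rng.random() * (1.0 - lo), 1e-16), 1.0 - 1e-16)
    draw = special.chdtri(df, 1.0 - q)
    if not np.isfinite(draw) or draw <= 0:
        return upper_sq * (1.0 - 1e-12)
    return min(ssq / draw, upper_sq * (1.0 - 1e-12))


def gibbs_sample(
    records: Sequence[PlotRecord],
    settings: MCMCSettings,
    priors: PriorSpec = PriorSpec(),
) -> PosteriorDraws:
    """Run the Gibbs sampler on complete-case records.

    Chains are initialized over-dispersed: effects at zero, all SDs at
    the sample SD of the response scaled by 0.5 / 1 / 2 cycling over
    chains.  Fully reproducible given ``settings.seed``.
    """
    frame = ModelFrame.from_records(records)
    y, x, n = frame.y, frame.x, frame.n
    sd_y = float(np.std(y, ddof=1))
    upper = priors.sd_upper if priors.sd_upper is not None else 10.0 * sd_y
    upper_sq = upper * upper
    loc_prec = 1.0 / priors.loc_scale**2
    x_sd = float(np.std(x, ddof=1))

    batch_meta = []
    for name in BATCHES:
        idx, coef, nlev = frame.batch_index(name)
        batch_meta.append((name, idx, coef, nlev))
    # composition index of each (site, composition) pair level, and the
    # number of plots behind each pair, for the blocked update
    pair_comp = np.array([comp for _, comp in frame.pair_levels], dtype=np.int64)
    n_pair_obs = np.bincount(frame.pair_idx, minlength=len(frame.pair_levels)).astype(float)
    comp_slot, pair_slot = BATCHES.index("composition"), BATCHES.index("experiment:composition")

    keep = settings.retained_per_chain
    nb = len(BATCHES)
    beta0_out = np.empty((settings.n_chains, keep))
    slope_out = np.empty((settings.n_chains, keep))
    effects_out = {name: np.empty((settings.n_chains, keep, nlev)) for name, _, _, nlev in batch_meta}
    sigma_out = {name: np.empty((settings.n_chains, keep)) for name, *_ in batch_meta}
    sigma_out["residual"] = np.empty((settings.n_chains, keep))
    s_out = {src: np.empty((settings.n_chains, keep)) for src in SOURCES}

    for chain in range(settings.n_chains):
        rng = np.random.default_rng([settings.seed, chain])
        disp = (0.5, 1.0, 2.0)[chain % 3]
        beta0 = float(y.mean())
        slope = 0.0
        effects = [np.zeros(nlev) for _, _, _, nlev in batch_meta]
        s2m = [min((disp * sd_y) ** 2, upper_sq * 0.99)] * nb
        s2e = min((disp * sd_y) ** 2, upper_sq * 0.99)

        # running residual r = y - fitted
        r = y - beta0 - slope * x
        for v, (_, idx, coef, _) in zip(effects, batch_meta):
            r -= coef * v[idx]

        kept = 0
        for it in range(1, settings.n_iter + 1):
            # grand mean
            partial = r + beta0
            prec = n / s2e + loc_prec
            beta0 = partial.sum() / s2e / prec + rng.standard_normal() / np.sqrt(prec)
            r = partial - beta0
            # overall slope
            partial = r + slope * x
            sxx = float(x @ x)
            prec = sxx / s2e + loc_prec
            slope = float(x @ partial) / s2e / prec + rng.standard_normal() / np.sqrt(prec)
            r = partial - slope * x
            # effect batches; composition and its site interaction jointly
            for m, (_, idx, coef, nlev) in enumerate(batch_meta):
                if m == pair_slot:
                    continue
                if m == comp_slot:
                    partial = (
                        r
                        + effects[comp_slot][frame.comp_idx]
                        + effects[pair_slot][frame.pair_idx]
                    )
                    c, g = _sample_comp_pair_joint(
                        rng, partial, frame.comp_idx, frame.pair_idx, pair_comp,
                        n_pair_obs, len(frame.comp_levels), len(frame.pair_levels),
                        s2e, s2m[comp_slot], s2m[pair_slot],
                    )
                    effects[comp_slot], effects[pair_slot] = c, g
                    r = partial - c[frame.comp_idx] - g[frame.pair_idx]
                    continue
                partial = r + coef * effects[m][idx]
                effects[m] = _sample_level_effects(rng, partial, idx, coef, nlev, s2e, s2m[m])
                r = partial - coef * effects[m][idx]
            # batch and residual variances
            for m, (_, _, _, nlev) in enumerate(batch_meta):
                s2m[m] = _sample_variance(
                    rng, float(effects[m] @ effects[m]), nlev, upper_sq, priors.family
                )
            s2e = _sample_variance(rng, float(r @ r), n, upper_sq, priors.family)
            if not np.isfinite(s2e) or s2e <= 0:
                raise FloatingPointError(f"residual variance overflow at iteration {it}")

            past = it - settings.burn_in
            if past > 0 and past % settings.thin == 0 and kept < keep:
                beta0_out[chain, kept] = beta0
                slope_out[chain, kept] = slope
                for m, (name, idx, coef, nlev) in enumerate(batch_meta):
                    effects_out[name][chain, kept] = effects[m]
                    sigma_out[name][chain, kept] = np.sqrt(s2m[m])
                sigma_out["residual"][chain, kept] = np.sqrt(s2e)
                s_out["experiment"][chain, kept] = np.std(effects[0], ddof=1)
                s_out["block"][chain, kept] = np.std(effects[1], ddof=1)
                s_out["composition"][chain, kept] = np.std(effects[2], ddof=1)
                s_out["richness"][chain, kept] = abs(slope) * x_sd
                s_out["experiment:richness"][chain, kept] = np.std(
                    effects[3][frame.site_idx] * x, ddof=1
                )
                s_out["experiment:composition"][chain, kept] = np.std(effects[4], ddof=1)
                s_out["residual"][chain, kept] = np.std(r, ddof=1)
                kept += 1

    return PosteriorDraws(
        settings=settings,
        priors=priors,
        beta0=beta0_out,
        slope=slope_out,
        effects=effects_out,
        sigma=sigma_out,
        s=s_out,
        x_sd=x_sd,
        level_names={
            "experiment": frame.site_levels,
            "block": frame.block_levels,
            "composition": frame.comp_levels,
            "experiment:richness": frame.site_levels,
            "experiment:composition": frame.pair_levels,
        },
    )


def rhat(chains: np.ndarray) -> float:
    """Potential scale reduction factor from >= 2 equal-length chains.

    sqrt(((n-1)/n * W + B/n) / W) with B the between-chain and W the
    within-chain variance.  Undefined (ValueError) when every chain has
    zero internal variance.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 10:
        raise ValueError("need >= 2 chains of equal length >= 10")
    n = chains.shape[1]
    means = chains.mean(axis=1)
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    B = float(n * np.var(means, ddof=1))
    if W == 0.0:
        raise ValueError("zero within-chain variance: R-hat undefined")
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def percent_shares(point_estimates: dict) -> dict:
    """Percent of the summed SD-scale point estimates per source."""
    total = sum(point_estimates.values())
    return {k: 100.0 * v / total for k, v in point_estimates.items()}


@dataclass
class ConvergenceReport:
    table: pd.DataFrame  # parameter, rhat, pass
    threshold: float
    converged: bool


def summarize_posterior(
    draws: PosteriorDraws,
    rhat_threshold: float = 1.1,
) -> tuple[pd.DataFrame, ConvergenceReport]:
    """Posterior summary of the finite-population SDs plus convergence.

    Per source: posterior median (the point estimate), posterior SD
    (reported as SE), the 2.5/16/84/97.5% quantiles, and the percent
    share of the summed medians.  Chains are pooled for the summary; if
    any monitored R-hat breaches the threshold the result carries a
    failed-convergence flag rather than raising.
    """
    rows = []
    for name, arr in draws.monitored().items():
        try:
            value = rhat(arr)
        except ValueError:
            value = np.nan
        rows.append({"parameter": name, "rhat": value, "pass": bool(value < rhat_threshold)})
    conv_table = pd.DataFrame(rows)
    converged = bool(conv_table["pass"].all())
    report = ConvergenceReport(table=conv_table, threshold=rhat_threshold, converged=converged)

    medians = {src: float(np.median(draws.s[src])) for src in SOURCES}
    shares = percent_shares(medians)
    out = []
    for src in SOURCES:
        pooled = draws.s[src].ravel()
        q = np.quantile(pooled, [0.025, 0.16, 0.84, 0.975])
        out.append(
            {
                "source": src,
                "sd_point": medians[src],
                "sd_se": float(np.std(pooled, ddof=1)),
                "q2_5": q[0],
                "q16": q[1],
                "q84": q[2],
                "q97_5": q[3],
                "percent_share": shares[src],
            }
        )
    summary = pd.DataFrame(out)
    summary.attrs["converged"] = converged
    summary.attrs["finite_population_note"] = (
        "richness rows use plot-level slope contributions; categorical rows use level effects"
    )
    return summary, report
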