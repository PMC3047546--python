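"""Least-squares multi-stratum ANOVA with Type-I sequential sums of squares.

Each term's SS is the squared norm of the response projection onto the
part of its column space not already spanned by earlier terms; degrees
of freedom are incremental ranks, so aliasing between terms (composition
columns partially absorbed by site and richness margins, for example) is
resolved purely numerically.
"""
from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import ModelFrame
from .study_data import PlotRecord

#: model term order for the sequential decomposition
DEFAULT_TERM_ORDER = (
    "experiment",
    "block",
    "richness",
    "composition",
    "experiment:richness",
    "experiment:composition",
)

#: unconstrained-school error strata: random main effects are tested
#: against their interaction with experiment, the fixed richness slope
#: against composition, and the remaining interactions against blocks or
#: the plot-level residual
DEFAULT_ERROR_MAP: Mapping[str, str] = {
    "experiment": "block",
    "block": "residual",
    "richness": "composition",
    "composition": "experiment:composition",
    "experiment:richness": "experiment:composition",
    "experiment:composition": "residual",
}

#: constrained school: random main effects go straight to the residual
CONSTRAINED_ERROR_MAP: Mapping[str, str] = {
    **DEFAULT_ERROR_MAP,
    "composition": "residual",
}

_RANK_RTOL = 1e-8


class SingularDesignError(ValueError):
    pass


@dataclass(frozen=True)
class SSRow:
    source: str
    df: int
    ss: float


@dataclass(frozen=True)
class SSResult:
    """Sequential decomposition: per-term rows plus residual and totals."""

    terms: tuple[SSRow, ...]
    residual_df: int
    residual_ss: float
    total_df: int
    total_ss: float  # corrected (about the mean)


def _term_columns(frame: ModelFrame, term: str) -> np.ndarray:
    if term == "richness":
        return frame.x[:, None].copy()
    return frame.z_matrix(term)


def sequential_ss(
    records: Sequence[PlotRecord],
    term_order: Sequence[str] = DEFAULT_TERM_ORDER,
) -> SSResult:
    """Type-I decomposition of the corrected total SS over ``term_order``.

    Rank detection: each term's columns are unit-scaled, residualized
    twice against the accumulated orthonormal basis, and SVD-filtered at
    ``1e-8`` of the leading singular value (with an absolute floor so a
    fully aliased term contributes rank 0, not noise).
    """
    frame = ModelFrame.from_records(records)
    y = frame.y
    n = frame.n
    if len(np.unique(y)) < 2:
        raise SingularDesignError("need >= 2 distinct response values")

    basis = np.full((n, 1), 1.0 / np.sqrt(n))  # intercept
    rows: list[SSRow] = []
    for term in term_order:
        X = _term_columns(frame, term)
        norms = np.linalg.norm(X, axis=0)
        keep = norms > 0
        X = X[:, keep] / norms[keep]
        if X.shape[1] == 0:
            rows.append(SSRow(term, 0, 0.0))
            continue
        for _ in range(2):  # re-orthogonalize for numerical safety
            X = X - basis @ (basis.T @ X)
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        tol = _RANK_RTOL * max(1.0, float(s[0])) if s.size else np.inf
        rank = int(np.sum(s > tol))
        Uk = U[:, :rank]
        proj = Uk.T @ y
        rows.append(SSRow(term, rank, float(proj @ proj)))
        if rank:
            basis = np.hstack([basis, Uk])

    total_ss = float(np.sum((y - y.mean()) ** 2))
    explained = sum(r.ss for r in rows)
    resid_df = n - 1 - sum(r.df for r in rows)
    resid_ss = max(total_ss - explained, 0.0)
    return SSResult(
        terms=tuple(rows),
        residual_df=resid_df,
        residual_ss=resid_ss,
        total_df=n - 1,
        total_ss=total_ss,
    )


def assemble_anova(
    ss_result: SSResult,
    error_map: Mapping[str, str] = DEFAULT_ERROR_MAP,
) -> pd.DataFrame:
    """Attach MS, F, P, error-term and R^2 columns to a decomposition.

    F divides each source's MS by the MS of its mapped error stratum; P is
    the upper tail of the F distribution; R^2 is the percent of the
    corrected total SS.  Sources whose error stratum has zero DF get no
    F or P.
    """
    ms: dict[str, float] = {}
    df: dict[str, int] = {}
    for row in ss_result.terms:
        df[row.source] = row.df
        ms[row.source] = row.ss / row.df if row.df > 0 else np.nan
    df["residual"] = ss_result.residual_df
    ms["residual"] = (
        ss_result.residual_ss / ss_result.residual_df if ss_result.residual_df > 0 else np.nan
    )
    for source, err in error_map.items():
        if err not in ms and err is not None:
            raise KeyError(f"error map names unknown term {err!r} for source {source!r}")

    out = []
    for row in ss_result.terms:
        err = error_map.get(row.source)
        f = p = np.nan
        if err is not None and row.df > 0 and df.get(err, 0) > 0 and np.isfinite(ms[err]) and ms[err] > 0:
            f = ms[row.source] / ms[err]
            p = float(stats.f.sf(f, row.df, df[err]))
        out.append(
            {
                "source": row.source,
                "df": row.df,
                "ss": row.ss,
                "ms": ms[row.source],
                "f": f,
                "p": p,
                "error_term": err if err is not None else "",
                "r2_percent": 100.0 * row.ss / ss_result.total_ss,
            }
        )
    out.append(
        {
            "source": "residual",
            "df": ss_result.residual_df,
            "ss": ss_result.residual_ss,
            "ms": ms["residual"],
            "f": np.nan,
            "p": np.nan,
            "error_term": "",
            "r2_percent": 100.0 * ss_result.residual_ss / ss_result.total_ss,
        }
    )
    out.append(
        {
            "source": "total",
            "df": ss_result.total_df,
            "ss": ss_result.total_ss,
            "ms": np.nan,
            "f": np.nan,
            "p": np.nan,
            "error_term": "",
            "r2_percent": 100.0,
        }
    )
    return pd.DataFrame(out)


def per_site_regression(records: Sequence[PlotRecord]) -> pd.DataFrame:
    """Within-site OLS of the response on log2 richness.

    Returns one row per site with slope, intercept, slope SE and the
    t-based 95% CI.  Sites with a single richness level are flagged
    non-estimable; two-level sites are estimable.
    """
    by_site: dict[str, list[PlotRecord]] = {}
    for rec in records:
        if not rec.is_missing:
            by_site.setdefault(rec.site_id, []).append(rec)
    rows = []
    for site_id in sorted(by_site):
        recs = by_site[site_id]
        x = np.log2([r.richness for r in recs])
        y = np.array([r.anpp for r in recs])
        n = len(recs)
        if len(np.unique(x)) < 2:
            rows.append(
                {
                    "site_id": site_id,
                    "n": n,
                    "estimable": False,
                    "slope": np.nan,
                    "intercept": np.nan,
                    "se": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
            continue
        xc = x - x.mean()
        sxx = float(xc @ xc)
        slope = float(xc @ y) / sxx
        intercept = float(y.mean() - slope * x.mean())
        resid = y - (intercept + slope * x)
        dof = n - 2
        if dof > 0:
            sigma2 = float(resid @ resid) / dof
            se = np.sqrt(sigma2 / sxx)
            tq = stats.t.ppf(0.975, dof)
            lo, hi = slope - tq * se, slope + tq * se
        else:
            se = lo = hi = np.nan
        rows.append(
            {
                "site_id": site_id,
                "n": n,
                "estimable": True,
                "slope": slope,
                "intercept": intercept,
                "se": se,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)
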