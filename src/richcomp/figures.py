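"""Matplotlib figures: graphical ANOVA and per-site slope panels."""
from __future__ import annotations

import logging
import math
from collections.abc import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .study_data import PlotRecord

logger = logging.getLogger(__name__)


def graphical_anova_plot(summary: pd.DataFrame, out) -> dict:
    """Render a variance-component summary as a graphical ANOVA.

    One row per source in model order: point estimate on the SD scale
    with nested 95% (wide, thin) and 68% (narrow, thick) horizontal
    intervals.
    """
    if len(summary) < 1:
        raise ValueError("summary has no source rows")
    n = len(summary)
    fig, ax = plt.subplots(figsize=(7, 0.6 * n + 1.5))
    ys = np.arange(n)[::-1]
    for y, (_, row) in zip(ys, summary.iterrows()):
        ax.hlines(y, row["q2_5"], row["q97_5"], color="0.4", lw=1.2)
        ax.hlines(y, row["q16"], row["q84"], color="0.1", lw=3.2)
        ax.plot(row["sd_point"], y, "o", color="black", ms=5)
    ax.set_yticks(ys)
    ax.set_yticklabels(summary["source"])
    ax.set_xlabel("finite-population SD (g m$^{-2}$ yr$^{-1}$)")
    ax.set_xlim(left=0)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return {"path": out, "n_rows": n}


def composition_means(records: Sequence[PlotRecord]) -> pd.DataFrame:
    """Mean response per (site, composition) with SEM = sd / sqrt(r).

    SEM is NaN for single-replicate compositions.
    """
    rows: dict = {}
    for rec in records:
        if rec.is_missing:
            continue
        key = (rec.site_id, rec.composition_label)
        rows.setdefault(key, {"richness": rec.richness, "values": []})["values"].append(rec.anpp)
    out = []
    for (site, label), entry in sorted(rows.items()):
        vals = np.asarray(entry["values"])
        sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else np.nan
        out.append(
            {
                "site_id": site,
                "composition_label": label,
                "richness": entry["richness"],
                "mean": float(vals.mean()),
                "sem": sem,
                "n": len(vals),
            }
        )
    return pd.DataFrame(out)


def slope_panels(
    records: Sequence[PlotRecord],
    ols: pd.DataFrame,
    out,
    mode: str = "ols",
    blup: pd.Series | None = None,
    overall_slope: float | None = None,
) -> dict:
    """One panel per site.

    ``mode="ols"``: plot-level points, the within-site OLS line and its
    95% confidence band.  ``mode="blup"``: composition means with SEM
    bars, the overall slope (red) and the shrunken per-site slope
    (black); both lines are anchored at the site's mean point.
    """
    if mode not in ("ols", "blup"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "blup" and (blup is None or overall_slope is None):
        raise ValueError("blup mode needs blup slopes and the overall slope")
    site_ids = list(ols["site_id"])
    if not site_ids:
        raise ValueError("no site fits supplied")
    ncol = 4
    nrow = math.ceil(len(site_ids) / ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False)
    by_site: dict[str, list[PlotRecord]] = {}
    for rec in records:
        if not rec.is_missing:
            by_site.setdefault(rec.site_id, []).append(rec)
    means = composition_means(records) if mode == "blup" else None

    for k, site_id in enumerate(site_ids):
        ax = axes[k // ncol][k % ncol]
        recs = by_site.get(site_id, [])
        xs = np.log2([r.richness for r in recs])
        ys = np.array([r.anpp for r in recs])
        fit = ols[ols["site_id"] == site_id].iloc[0]
        if mode == "ols":
            ax.plot(xs, ys, "o", ms=3, alpha=0.6)
            if fit["estimable"] and np.isfinite(fit["slope"]):
                grid = np.linspace(xs.min(), xs.max(), 50)
                line = fit["intercept"] + fit["slope"] * grid
                ax.plot(grid, line, color="C3")
                if np.isfinite(fit["se"]) and len(recs) > 2:
                    xc = xs - xs.mean()
                    sxx = float(xc @ xc)
                    resid = ys - (fit["intercept"] + fit["slope"] * xs)
                    sigma2 = float(resid @ resid) / (len(recs) - 2)
                    se_line = np.sqrt(sigma2 * (1.0 / len(recs) + (grid - xs.mean()) ** 2 / sxx))
                    tq = stats.t.ppf(0.975, len(recs) - 2)
                    ax.fill_between(grid, line - tq * se_line, line + tq * se_line, alpha=0.2)
            else:
                logger.warning("site %s: slope not estimable, panel drawn without line", site_id)
        else:
            sub = means[means["site_id"] == site_id]
            ax.errorbar(
                np.log2(sub["richness"]), sub["mean"], yerr=sub["sem"].values,
                fmt="o", ms=3, alpha=0.7, lw=1,
            )
            x0, y0 = xs.mean(), ys.mean()
            grid = np.linspace(xs.min(), xs.max(), 50)
            ax.plot(grid, y0 + overall_slope * (grid - x0), color="C3", label="overall")
            if site_id in blup.index:
                ax.plot(grid, y0 + blup[site_id] * (grid - x0), color="black", label="site BLUP")
        ax.set_title(site_id, fontsize=9)
    for k in range(len(site_ids), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.supxlabel("log2 species richness")
    fig.supylabel("ANPP (g m$^{-2}$ yr$^{-1}$)")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return {"path": out, "n_panels": len(site_ids)}
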