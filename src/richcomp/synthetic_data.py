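"""Forward simulator for the hierarchical ANPP model on multi-site skeletons.

A skeleton is a set of plots without responses: sites with blocks, a
richness gradient, compositions replicated within sites and optionally
shared across sites.  Responses are simulated as a grand mean plus
independent zero-mean normal effect batches (site, block, per-site
richness-slope deviations, composition, site x composition) plus a
richness slope on the centered log2 scale and iid residual noise.
"""
from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .study_data import PlotRecord, EmptyDataError


class ConfigError(ValueError):
    """Skeleton or truth configuration is not realizable."""


@dataclass(frozen=True)
class TruthParams:
    """Generative parameter set.

    Slope-scale quantities (``mean_slope``, ``sd_richness_site``) are per
    unit of centered log2 richness; all other SDs are on the response
    scale (g m^-2 yr^-1).
    """

    grand_mean: float
    mean_slope: float
    sd_experiment: float
    sd_block: float
    sd_richness_site: float
    sd_composition: float
    sd_exp_composition: float
    sd_residual: float

    def __post_init__(self) -> None:
        for name in (
            "sd_experiment",
            "sd_block",
            "sd_richness_site",
            "sd_composition",
            "sd_exp_composition",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.sd_residual < 0:
            raise ConfigError("sd_residual must be >= 0")


@dataclass(frozen=True)
class SiteConfig:
    site_id: str
    n_blocks: int
    richness_levels: tuple[int, ...]
    n_compositions: int
    n_plots: int


#: 12-site reference layout: 778 plots, 29 blocks, 359 site-local
#: compositions, richness gradients from monocultures up to 32 species
REFERENCE_DESIGN: tuple[SiteConfig, ...] = (
    SiteConfig("site01", 6, (1, 8), 9, 54),
    SiteConfig("site02", 1, (1, 2, 4, 8, 14), 27, 56),
    SiteConfig("site03", 3, (1, 4, 16), 21, 56),
    SiteConfig("site04", 2, (1, 2, 4, 8, 18), 26, 52),
    SiteConfig("site05", 2, (1, 2, 4, 8, 12), 28, 58),
    SiteConfig("site06", 4, (1, 2, 4, 8, 16), 78, 156),
    SiteConfig("site07", 2, (1, 2, 4, 8, 32), 32, 64),
    SiteConfig("site08", 2, (1, 2, 4, 8, 12), 26, 54),
    SiteConfig("site09", 2, (1, 2, 4, 8, 11), 33, 66),
    SiteConfig("site10", 1, (1, 4), 16, 32),
    SiteConfig("site11", 2, (1, 2, 3, 4, 8), 33, 70),
    SiteConfig("site12", 2, (1, 2, 4, 8, 16), 30, 60),
)

#: calibration targets on the finite-population SD scale (response units)
DEFAULT_SD_SCALE = {
    "experiment": 96.5,
    "block": 26.0,
    "richness": 111.2,
    "composition": 114.2,
    "experiment:richness": 80.3,
    "experiment:composition": 101.1,
    "residual": 116.5,
}

# Every fitted quantity in this package is invariant to the response
# location.  The default grand mean is set high enough that Gaussian
# draws with the default SD magnitudes (total SD ~ 256) essentially
# never go negative, keeping simulated ANPP physically valid.
DEFAULT_GRAND_MEAN = 1500.0


@dataclass
class DesignSkeleton:
    """Plots without responses plus the species membership behind each code."""

    records: list[PlotRecord]
    species_sets: dict  # (site_id, composition_label) -> frozenset of species
    sharing_fraction: float
    seed: int

    @property
    def n_global_codes(self) -> int:
        return len({r.composition_code for r in self.records})

    def species_table(self) -> pd.DataFrame:
        rows = [
            {"site": site, "composition_label": label, "species": sp}
            for (site, label), members in sorted(self.species_sets.items())
            for sp in sorted(members)
        ]
        return pd.DataFrame(rows)

    def centered_log2_richness(self) -> np.ndarray:
        logr = np.log2([r.richness for r in self.records])
        return logr - logr.mean()


def _split_evenly(total: int, n_bins: int) -> list[int]:
    base, extra = divmod(total, n_bins)
    return [base + (1 if i < extra else 0) for i in range(n_bins)]


def build_skeleton(
    sites: Sequence[SiteConfig] = REFERENCE_DESIGN,
    sharing_fraction: float = 0.0,
    seed: int = 0,
    species_pool: int = 2000,
) -> DesignSkeleton:
    """Build a deterministic multi-site design skeleton.

    Per site, compositions are spread as evenly as possible over the
    richness levels and plots as evenly as possible over compositions;
    plots rotate through the site's blocks.  With probability
    ``sharing_fraction`` a composition reuses an existing global code of
    equal richness from another site (so shared codes always appear at
    two or more sites).
    """
    if not 0.0 <= sharing_fraction <= 1.0:
        raise ConfigError("sharing_fraction must lie in [0, 1]")
    if sharing_fraction > 0:
        level_sites: dict[int, int] = {}
        for cfg in sites:
            for lev in cfg.richness_levels:
                level_sites[lev] = level_sites.get(lev, 0) + 1
        if all(count < 2 for count in level_sites.values()):
            raise ConfigError("sharing requested but no richness level occurs at >= 2 sites")

    rng = np.random.default_rng(seed)
    pool = [f"sp{i:04d}" for i in range(species_pool)]
    known_sets: set[frozenset] = set()
    # global code registry: richness -> list of (code, species set, sites using it)
    by_richness: dict[int, list[list]] = {}
    next_code = 1

    records: list[PlotRecord] = []
    species_sets: dict = {}
    for cfg in sites:
        levels = sorted(cfg.richness_levels)
        if cfg.n_compositions < len(levels):
            raise ConfigError(f"{cfg.site_id}: fewer compositions than richness levels")
        if cfg.n_plots < cfg.n_compositions:
            raise ConfigError(f"{cfg.site_id}: fewer plots than compositions")
        per_level = _split_evenly(cfg.n_compositions, len(levels))
        comp_specs: list[tuple[str, int, int]] = []  # (label, richness, code)
        comp_no = 0
        for richness, count in zip(levels, per_level):
            for _ in range(count):
                comp_no += 1
                label = f"c{comp_no:03d}"
                candidates = [
                    entry
                    for entry in by_richness.get(richness, [])
                    if cfg.site_id not in entry[2]
                ]
                if candidates and rng.random() < sharing_fraction:
                    entry = candidates[rng.integers(len(candidates))]
                    entry[2].add(cfg.site_id)
                    code, members = entry[0], entry[1]
                else:
                    members = None
                    for _attempt in range(1000):
                        draw = frozenset(rng.choice(len(pool), size=richness, replace=False).tolist())
                        cand = frozenset(pool[i] for i in draw)
                        if cand not in known_sets:
                            members = cand
                            break
                    if members is None:
                        raise ConfigError("species pool exhausted; increase species_pool")
                    known_sets.add(members)
                    code = next_code
                    next_code += 1
                    by_richness.setdefault(richness, []).append([code, members, {cfg.site_id}])
                comp_specs.append((label, richness, code))
                species_sets[(cfg.site_id, label)] = members
        reps = _split_evenly(cfg.n_plots, cfg.n_compositions)
        plot_no = 0
        for (label, richness, code), r in zip(comp_specs, reps):
            for _ in range(r):
                plot_no += 1
                block = f"b{(plot_no - 1) % cfg.n_blocks + 1}"
                records.append(
                    PlotRecord(
                        site_id=cfg.site_id,
                        block_id=block,
                        plot_id=f"{cfg.site_id}-p{plot_no:03d}",
                        richness=richness,
                        composition_label=label,
                        composition_code=code,
                        anpp=None,
                    )
                )
    return DesignSkeleton(
        records=records,
        species_sets=species_sets,
        sharing_fraction=sharing_fraction,
        seed=seed,
    )


def tune_sharing_fraction(
    sites: Sequence[SiteConfig] = REFERENCE_DESIGN,
    target_global_codes: int = 308,
    seed: int = 0,
    n_grid: int = 81,
) -> tuple[float, DesignSkeleton]:
    """Grid-search the sharing fraction whose skeleton lands closest to a
    target global composition count; ties break toward the smaller fraction."""
    best = None
    for frac in np.linspace(0.0, 0.8, n_grid):
        skel = build_skeleton(sites, sharing_fraction=float(frac), seed=seed)
        gap = abs(skel.n_global_codes - target_global_codes)
        if best is None or gap < best[0]:
            best = (gap, float(frac), skel)
        if gap == 0:
            break
    return best[1], best[2]


def calibrated_truth(
    skeleton: DesignSkeleton,
    sd_scale: dict | None = None,
    grand_mean: float = DEFAULT_GRAND_MEAN,
) -> TruthParams:
    """Convert response-scale SD targets into generative parameters.

    The richness and site-richness entries are finite-population SDs of
    plot-level slope contributions, so they are divided by the SD of the
    skeleton's centered log2 richness to land on the slope scale.  This
    is a calibration convenience, not an exact inversion.
    """
    sd_scale = dict(DEFAULT_SD_SCALE if sd_scale is None else sd_scale)
    sx = float(np.std(skeleton.centered_log2_richness(), ddof=1))
    if sx <= 0:
        raise ConfigError("skeleton has a single richness level; cannot calibrate slopes")
    return TruthParams(
        grand_mean=grand_mean,
        mean_slope=sd_scale["richness"] / sx,
        sd_experiment=sd_scale["experiment"],
        sd_block=sd_scale["block"],
        sd_richness_site=sd_scale["experiment:richness"] / sx,
        sd_composition=sd_scale["composition"],
        sd_exp_composition=sd_scale["experiment:composition"],
        sd_residual=sd_scale["residual"],
    )


@dataclass
class SimulatedDataset:
    """Simulated records plus the realized effects behind them.

    ``finite_pop_sds`` uses the effects exactly as drawn.  For the two
    slope-based sources the overall slope and the mean of the per-site
    slope deviations are only jointly identified by the fitted model
    (the deviations' prior centers them at zero), so
    ``identified_finite_pop_sds`` re-attributes the realized deviation
    mean to the richness source -- the decomposition an estimator can
    actually recover.  Categorical sources are identical in both.
    """

    records: list[PlotRecord]
    truth: TruthParams
    effects: dict  # batch name -> realized effect vector (and "residual")
    finite_pop_sds: dict  # source name -> realized finite-population SD
    identified_finite_pop_sds: dict
    x_center: float


def simulate_responses(
    skeleton: DesignSkeleton,
    truth: TruthParams,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> SimulatedDataset:
    """Draw one response vector from the generative model.

    Effects are drawn once per level of each batch; the response is the
    additive combination plus iid residual noise.  ``missing_rate``
    blanks responses completely at random.  Deterministic given ``seed``.
    """
    from .design import ModelFrame  # local import to avoid cycle at module load

    if not skeleton.records:
        raise EmptyDataError("empty skeleton")
    rng = np.random.default_rng(seed)
    probe = [replace(r, anpp=0.0) for r in skeleton.records]
    frame = ModelFrame.from_records(probe)
    x = frame.x

    n_site = len(frame.site_levels)
    n_block = len(frame.block_levels)
    n_comp = len(frame.comp_levels)
    n_pair = len(frame.pair_levels)

    a = rng.normal(0.0, truth.sd_experiment, n_site)
    b = rng.normal(0.0, truth.sd_block, n_block)
    c = rng.normal(0.0, truth.sd_composition, n_comp)
    d = rng.normal(0.0, truth.sd_richness_site, n_site)
    g = rng.normal(0.0, truth.sd_exp_composition, n_pair)
    eps = rng.normal(0.0, truth.sd_residual, frame.n)

    mu = (
        truth.grand_mean
        + a[frame.site_idx]
        + b[frame.block_idx]
        + (truth.mean_slope + d[frame.site_idx]) * x
        + c[frame.comp_idx]
        + g[frame.pair_idx]
    )
    anpp = mu + eps

    missing = np.zeros(frame.n, dtype=bool)
    if missing_rate > 0:
        missing = rng.random(frame.n) < missing_rate

    records = [
        replace(rec, anpp=None if missing[i] else float(anpp[i]))
        for i, rec in enumerate(skeleton.records)
    ]

    def _fps(v: np.ndarray) -> float:
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    effects = {
        "experiment": a,
        "block": b,
        "composition": c,
        "experiment:richness": d,
        "experiment:composition": g,
        "residual": eps,
    }
    finite_pop_sds = {
        "experiment": _fps(a),
        "block": _fps(b),
        "richness": _fps(truth.mean_slope * x),
        "composition": _fps(c),
        "experiment:richness": _fps(d[frame.site_idx] * x),
        "experiment:composition": _fps(g),
        "residual": _fps(eps),
    }
    d_mean = float(d.mean())
    identified = dict(finite_pop_sds)
    identified["richness"] = _fps((truth.mean_slope + d_mean) * x)
    identified["experiment:richness"] = _fps((d - d_mean)[frame.site_idx] * x)
    return SimulatedDataset(
        records=records,
        truth=truth,
        effects=effects,
        finite_pop_sds=finite_pop_sds,
        identified_finite_pop_sds=identified,
        x_center=frame.x_center,
    )
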