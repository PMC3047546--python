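"""End-to-end pipeline: simulate -> anova -> reml -> bayes -> figures.

Driven by a YAML/dict config; every stage writes machine-readable CSV
next to the text report, and each table carries the input dataset's
checksum in the bundle metadata.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .gibbs_anova import MCMCSettings, PriorSpec, gibbs_sample, summarize_posterior
from .reml_varcomp import (
    OptimizerSettings,
    blup_slopes,
    fixed_effect_anova,
    lrt_random_term,
    reml_fit,
    varcomp_table,
)
from .stratified_anova import (
    CONSTRAINED_ERROR_MAP,
    DEFAULT_ERROR_MAP,
    assemble_anova,
    per_site_regression,
    sequential_ss,
)
from .study_data import complete_cases, read_dataset, write_dataset
from .synthetic_data import (
    REFERENCE_DESIGN,
    build_skeleton,
    calibrated_truth,
    simulate_responses,
)
from . import figures

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "anova", "reml", "bayes", "figures")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ReportBundle:
    out_dir: Path
    input_checksum: str
    tables: dict = field(default_factory=dict)  # name -> csv path
    figures: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    with open(config) as fh:
        return yaml.safe_load(fh)


def _resolve_input(cfg: dict, out_dir: Path, seed: int) -> Path:
    source = cfg.get("input", {})
    if "csv" in source:
        return Path(source["csv"])
    syn = source.get("synthetic", {})
    skel = build_skeleton(
        REFERENCE_DESIGN,
        sharing_fraction=float(syn.get("sharing_fraction", 0.15)),
        seed=int(syn.get("seed", seed)),
    )
    truth = calibrated_truth(skel, syn.get("sd_scale"))
    sim = simulate_responses(skel, truth, seed=int(syn.get("seed", seed)))
    path = out_dir / "simulated.csv"
    write_dataset(sim.records, path)
    return path


def run_pipeline(config, out_dir=None) -> ReportBundle:
    """Execute the configured stages; abort on the first failing stage,
    naming it and preserving whatever completed before it."""
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    out_dir = Path(out_dir or cfg.get("out", "richcomp_report"))
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = tuple(cfg.get("stages", ALL_STAGES))

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("richcomp")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    try:
        if "simulate" in stages or "csv" not in cfg.get("input", {}):
            try:
                data_path = _resolve_input(cfg, out_dir, seed)
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError("simulate", exc) from exc
        else:
            data_path = Path(cfg["input"]["csv"])

        checksum = _checksum(data_path)
        bundle = ReportBundle(out_dir=out_dir, input_checksum=checksum)
        bundle.metadata = {
            "input": str(data_path),
            "input_sha256": checksum,
            "seed": seed,
            "stages": list(stages),
            "version": __version__,
        }
        records = complete_cases(read_dataset(data_path))

        def save(name: str, frame: pd.DataFrame) -> Path:
            path = out_dir / f"{name}.csv"
            frame.to_csv(path, index=False)
            bundle.tables[name] = path
            return path

        fit = None
        summary = None
        ols = None

        if "anova" in stages:
            try:
                error_map = DEFAULT_ERROR_MAP
                if cfg.get("anova", {}).get("error_map") == "constrained":
                    error_map = CONSTRAINED_ERROR_MAP
                table = assemble_anova(sequential_ss(records), error_map)
                save("anova_table", table)
                ols = per_site_regression(records)
                save("per_site_slopes", ols)
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError("anova", exc) from exc

        if "reml" in stages:
            try:
                opt = OptimizerSettings(n_starts=int(cfg.get("reml", {}).get("n_starts", 3)))
                fit = reml_fit(records, settings=opt)
                save("reml_varcomps", varcomp_table(fit))
                fe = fixed_effect_anova(fit)
                save(
                    "reml_fixed_effects",
                    pd.DataFrame(
                        [{"source": fe.source, "df": fe.df, "ss": fe.ss, "ms": fe.ms, "f": fe.f}]
                    ),
                )
                save("reml_blup_slopes", blup_slopes(fit).rename_axis("site_id").reset_index())
                if cfg.get("reml", {}).get("lrt", False):
                    lrt_rows = []
                    for term in fit.terms:
                        res = lrt_random_term(records, fit.terms, term, opt)
                        lrt_rows.append(vars(res))
                    save("reml_lrt", pd.DataFrame(lrt_rows))
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError("reml", exc) from exc

        if "bayes" in stages:
            try:
                bcfg = cfg.get("bayes", {})
                settings = MCMCSettings(
                    n_chains=int(bcfg.get("chains", 3)),
                    n_iter=int(bcfg.get("iter", 20_000)),
                    burn_in=int(bcfg.get("burn_in", 2_000)),
                    thin=int(bcfg.get("thin", 20)),
                    seed=int(bcfg.get("seed", seed)),
                )
                priors = PriorSpec(family=bcfg.get("prior", "uniform_sd"))
                draws = gibbs_sample(records, settings, priors)
                summary, report = summarize_posterior(draws)
                save("varcomp_summary", summary)
                save("convergence", report.table)
                bundle.metadata["bayes_converged"] = report.converged
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError("bayes", exc) from exc

        if "figures" in stages:
            try:
                if summary is not None:
                    path = out_dir / "graphical_anova.png"
                    figures.graphical_anova_plot(summary, path)
                    bundle.figures["graphical_anova"] = path
                if ols is None:
                    ols = per_site_regression(records)
                path = out_dir / "slopes_ols.png"
                figures.slope_panels(records, ols, path, mode="ols")
                bundle.figures["slopes_ols"] = path
                if fit is not None:
                    path = out_dir / "slopes_blup.png"
                    figures.slope_panels(
                        records,
                        ols,
                        path,
                        mode="blup",
                        blup=blup_slopes(fit),
                        overall_slope=float(fit.beta[1]),
                    )
                    bundle.figures["slopes_blup"] = path
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError("figures", exc) from exc

        (out_dir / "metadata.json").write_text(json.dumps(bundle.metadata, indent=2))
        return bundle
    finally:
        root.removeHandler(handler)
        handler.close()
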