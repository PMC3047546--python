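"""Shared fixtures: all test data is generated programmatically."""
from __future__ import annotations

import numpy as np
import pytest

from richcomp.reml_varcomp import OptimizerSettings, reml_fit
from richcomp.study_data import PlotRecord
from richcomp.synthetic_data import (
    REFERENCE_DESIGN,
    SiteConfig,
    TruthParams,
    build_skeleton,
    calibrated_truth,
    simulate_responses,
    tune_sharing_fraction,
)


@pytest.fixture(scope="session")
def reference_skeleton():
    """The 12-site reference layout with sharing tuned to ~308 global codes."""
    _, skeleton = tune_sharing_fraction(REFERENCE_DESIGN, target_global_codes=308, seed=1)
    return skeleton


@pytest.fixture(scope="session")
def reference_sim(reference_skeleton):
    truth = calibrated_truth(reference_skeleton)
    return simulate_responses(reference_skeleton, truth, seed=2)


@pytest.fixture(scope="session")
def reference_reml_fit(reference_sim):
    return reml_fit(reference_sim.records, settings=OptimizerSettings(n_starts=1))


SMALL_DESIGN = tuple(
    SiteConfig(f"s{i:02d}", 2, (1, 2, 4, 8), 8, 16) for i in range(1, 7)
)

SMALL_TRUTH = TruthParams(
    grand_mean=900.0,
    mean_slope=60.0,
    sd_experiment=80.0,
    sd_block=30.0,
    sd_richness_site=25.0,
    sd_composition=70.0,
    sd_exp_composition=50.0,
    sd_residual=45.0,
)


@pytest.fixture(scope="session")
def small_skeleton():
    """6 sites x 2 blocks x 16 plots: fast enough for repeated fitting."""
    return build_skeleton(SMALL_DESIGN, sharing_fraction=0.4, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_skeleton):
    return simulate_responses(small_skeleton, SMALL_TRUTH, seed=11)


def one_way_records(group_means, n_rep, noise_sd=0.0, seed=0) -> list[PlotRecord]:
    """Balanced one-way layout through the model's terms: one block and
    one shared composition per site, constant richness, so only the
    `experiment` batch carries structure."""
    rng = np.random.default_rng(seed)
    records = []
    for g, mu in enumerate(group_means):
        for r in range(n_rep):
            records.append(
                PlotRecord(
                    site_id=f"g{g:02d}",
                    block_id="b1",
                    plot_id=f"g{g:02d}-p{r}",
                    richness=1,
                    composition_label="mono",
                    composition_code=1,
                    anpp=float(mu + noise_sd * rng.standard_normal()),
                )
            )
    return records
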