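"""Shared fixtures: one synthetic study world reused across the suite.

The session world is the analysis-scale study condition (60x120 grid,
40 ecoregions, 10 blocks); fitting and importance fixtures are scoped
to the session so the expensive forest work happens once.
"""

from __future__ import annotations

import numpy as np
import pytest

import threatgrid as tg
from threatgrid import EffectTerm

WORLD_SEED = 7
BLOCK_SEED = 1
FIT_SEED = 2
VI_SEED = 3

# scaled analysis conditions used throughout the suite
NT = 1000
M = 3
N_REPEATS = 10


def planted_effect_spec() -> tg.SpeciesEffectSpec:
    """Threatened richness driven by total richness plus 3 planted covariates.

    Total richness itself is homogeneous (intercept-only baseline), so
    every covariate other than the three planted drivers is a genuine
    null for the threatened response.  Effect multipliers are calibrated
    so each planted term contributes ~1 SD on the logit scale (the
    asymptotic form saturates, so its multiplier is larger).
    """
    return tg.default_effect_spec(
        baseline_total_response=(),
        threatened_effects=(
            EffectTerm("elevation_sd", "linear+", 1.2),
            EffectTerm("annual_precipitation", "asymptotic", 4.0),
            EffectTerm("human_landuse_area", "linear+", 1.0),
        ),
    )


PLANTED_DRIVERS = frozenset(
    {"elevation_sd", "annual_precipitation", "human_landuse_area"}
)


@pytest.fixture(scope="session")
def world_config() -> tg.WorldConfig:
    return tg.WorldConfig(seed=WORLD_SEED)


@pytest.fixture(scope="session")
def world(world_config):
    return tg.generate_world(world_config)


@pytest.fixture(scope="session")
def covariates(world, world_config):
    return tg.generate_covariates(world, world_config)


@pytest.fixture(scope="session")
def assignment(world, covariates):
    units = tg.sampling_units(world)
    return tg.assign_blocks(units, covariates, k=10, seed=BLOCK_SEED)


@pytest.fixture(scope="session")
def folds(assignment):
    return tg.blocked_folds(assignment)


@pytest.fixture(scope="session")
def planted_richness(world, covariates):
    richness, truth = tg.generate_species(
        world, covariates, planted_effect_spec(), seed=WORLD_SEED
    )
    return richness, truth


@pytest.fixture(scope="session")
def planted_data(covariates, planted_richness):
    richness, _ = planted_richness
    return tg.model_frame(covariates, richness, "combined")


@pytest.fixture(scope="session")
def planted_ensemble(planted_data, folds, covariates):
    return tg.fit_cv_ensemble(
        planted_data,
        folds,
        m=M,
        nt=NT,
        response="threatened_richness",
        covariate_names=covariates.names + ["total_richness"],
        seed=FIT_SEED,
    )


@pytest.fixture(scope="session")
def planted_importance(planted_ensemble, planted_data, covariates):
    return tg.importance_table(
        planted_ensemble,
        planted_data,
        categories=covariates.categories,
        n_repeats=N_REPEATS,
        seed=VI_SEED,
    )


@pytest.fixture(scope="session")
def default_richness(world, covariates):
    """Counts from the package's default generative recipe (baseline
    drivers for total richness included) — used for the paired response
    curves, where total richness must respond unimodally to human land
    use while threatened richness responds monotonically."""
    richness, truth = tg.generate_species(world, covariates, seed=WORLD_SEED)
    return richness, truth


@pytest.fixture(scope="session")
def small_world():
    cfg = tg.WorldConfig(
        seed=11, grid_rows=24, grid_cols=30, n_ecoregions=12, n_regions=3
    )
    return cfg, tg.generate_world(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
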