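"""Shared fixtures: the synthetic toy network, planted multi-omics, and
pipeline runs reused across test modules (session-scoped; all seeded)."""

from __future__ import annotations

import pytest

from fluxcord.pipeline import PipelineParams, run_pipeline
from fluxcord.synthetic import (
    default_scenario,
    generate_planted_omics,
    generate_toy_model,
    zero_effect_scenario,
)

SEED = 1


def one_dof_model():
    """A single free flux on [0, 10]: uptake -> transport -> demand."""
    from fluxcord.model import (
        MetabolicModel,
        Reaction,
        Species,
        flag_exchanges,
        make_irreversible,
    )

    model = MetabolicModel(
        species=[Species("A_e", "A", "e"), Species("A_c", "A", "c")],
        reactions=[
            Reaction("EX_A", {"A_e": -1}, -10, 0),
            Reaction("T_A", {"A_e": -1, "A_c": 1}, 0, 1000),
            Reaction("DM_A", {"A_c": -1}, 0, 1000),
        ],
    )
    flag_exchanges(model)
    return make_irreversible(model)


@pytest.fixture(scope="session")
def toy_model():
    return generate_toy_model(n_branches=12, with_compartments=True)


@pytest.fixture(scope="session")
def planted(toy_model):
    scenario = default_scenario(toy_model, noise_sd=0.1, n_samples=3, seed=SEED)
    return scenario, generate_planted_omics(toy_model, scenario)


def _run(model, data, n_total, seed=SEED, **overrides):
    params = PipelineParams(
        n_samples_total=n_total, n_batches=10, thinning=10, seed=seed, **overrides
    )
    return run_pipeline(
        model,
        data.expression,
        data.metabolomics,
        medium=data.medium,
        spent=data.spent,
        exchange_map=data.exchange_map,
        biomass_id=data.biomass_id,
        glucose_exchange_id=data.glucose_exchange_id,
        params=params,
    )


@pytest.fixture(scope="session")
def planted_run(toy_model, planted):
    """Full pipeline on the planted fixture at 20,000 flux samples/group."""
    _, data = planted
    return _run(toy_model, data, n_total=20000)


@pytest.fixture(scope="session")
def batch_run(toy_model, planted):
    """Pipeline run with 10 sampling batches of 5,000 each per group."""
    _, data = planted
    return _run(toy_model, data, n_total=50000)


@pytest.fixture(scope="session")
def zero_run(toy_model):
    """Pipeline on a scenario with no planted effects anywhere."""
    scenario = zero_effect_scenario(toy_model, seed=SEED)
    data = generate_planted_omics(toy_model, scenario)
    return _run(toy_model, data, n_total=20000)
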