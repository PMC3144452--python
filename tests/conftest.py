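"""Shared fixtures: the study population, census fits and scenario runs.

Heavy Monte-Carlo objects are session-scoped and lazily cached so that the
acceptance tests can share one 52,750-person population, one set of census
reference fits and one run per scenario cell.
"""

import numpy as np
import pytest

from stratcox import (
    DesignSpec,
    LossSpec,
    ModelSpec,
    PopulationSpec,
    ScenarioSpec,
    generate_population,
    population_reference_fit,
    run_replications,
)

# frozen once for the whole suite: the population draw and the replication root
POP_SEED = 12345
ROOT_SEED = 777

PAPER_ALLOCATION = {"professionals": 3000, "technicians": 4500, "administrative": 7500}
DIFFERENTIAL_RATES = {"professionals": 0.08, "technicians": 0.12, "administrative": 0.20}

LOSSES = {
    "noloss": LossSpec("none"),
    "randloss": LossSpec("random", rate=0.15),
    "diffloss": LossSpec("differential", rates_by_stratum=DIFFERENTIAL_RATES),
}


@pytest.fixture(scope="session")
def paper_spec():
    """The default 52,750-person three-stratum population specification."""
    return PopulationSpec()


@pytest.fixture(scope="session")
def paper_pop(paper_spec):
    return generate_population(paper_spec, POP_SEED)


@pytest.fixture(scope="session")
def census(paper_pop):
    """Lazily cached census (whole-population, unit-weight) reference fits."""
    cache = {}

    def get(model_name: str):
        if model_name not in cache:
            cache[model_name] = population_reference_fit(paper_pop, ModelSpec(model_name))
        return cache[model_name]

    return get


@pytest.fixture(scope="session")
def scenario_runs(paper_pop):
    """Lazily cached replication runs on the stratified design.

    Key: (model, weighting, loss-name).  All runs share ROOT_SEED, so the
    underlying samples are identical across cells (paired comparisons).
    """
    cache = {}
    design = DesignSpec("stratified", allocation=PAPER_ALLOCATION)

    def get(model: str, weighting: str, loss: str, replicates: int = 200):
        key = (model, weighting, loss, replicates)
        if key not in cache:
            scenario = ScenarioSpec(
                name=f"strat_{model}_{weighting}_{loss}",
                design=design,
                loss=LOSSES[loss],
                model=ModelSpec(model),
                weighting=weighting,
                replicates=replicates,
                seed=ROOT_SEED,
            )
            cache[key] = run_replications(paper_pop, scenario)
        return cache[key]

    return get


@pytest.fixture
def rng():
    return np.random.default_rng(0)
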