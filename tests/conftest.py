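"""Shared fixtures: one small synthetic universe reused across test modules."""

import warnings

import pytest

from sigrepo.diffexpr import ModeratedTTest
from sigrepo.simulate import (
    SimulationConfig,
    gen_compound_knowledgebase,
    gen_expression_cohort,
    gen_gene_sets,
    gen_signature_library,
)


@pytest.fixture(scope="session")
def universe():
    """Default synthetic universe (cohort, truth, gene sets, library, KB)."""
    cfg = SimulationConfig(seed=42)
    dataset, truth = gen_expression_cohort(cfg)
    collection = gen_gene_sets(cfg)
    library = gen_signature_library(truth, cfg)
    kb = gen_compound_knowledgebase(truth, cfg, collection)
    return {"config": cfg, "dataset": dataset, "truth": truth,
            "collection": collection, "library": library, "kb": kb}


@pytest.fixture(scope="session")
def gene_stats(universe):
    """Moderated-t table for the NAFL vs Healthy contrast of the universe."""
    est = ModeratedTTest(contrast=("NAFL", "Healthy")).fit(universe["dataset"])
    return est.results_


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield
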