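"""Shared fixtures: packaged reference objects and one seeded study run.

The expensive objects (annotator, study catalogue, full pipeline manifest)
are session-scoped; every test that needs the end-to-end numbers reads the
same manifest instead of re-running the pipeline.
"""

from __future__ import annotations

import numpy as np
import pytest

from mitosoma import (
    filter_rna_confirmed,
    load_cloverleafs,
    load_features,
    load_genome,
)
from mitosoma.annotation import Annotator, annotate_catalogue
from mitosoma.pipeline import run_all
from mitosoma.simulate import study_catalogue

STUDY_SEED = 11


@pytest.fixture(scope="session")
def genome():
    return load_genome()


@pytest.fixture(scope="session")
def features():
    return load_features()


@pytest.fixture(scope="session")
def cloverleafs():
    return load_cloverleafs()


@pytest.fixture(scope="session")
def annotator(genome, features):
    return Annotator(genome, features)


@pytest.fixture(scope="session")
def study(genome, features):
    """(full 644-record catalogue, truth table) under the study conditions."""
    return study_catalogue(STUDY_SEED, genome, features)


@pytest.fixture(scope="session")
def confirmed(study):
    return filter_rna_confirmed(study[0])


@pytest.fixture(scope="session")
def annotated(confirmed, genome, features, annotator):
    return annotate_catalogue(confirmed, genome, features, annotator)


@pytest.fixture(scope="session")
def manifest(study, genome, features, cloverleafs):
    """One full pipeline run on the study catalogue (shared across tests)."""
    return run_all(
        study[0],
        seed=STUDY_SEED,
        genome=genome,
        features=features,
        cloverleafs=cloverleafs,
        shuffles=20,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
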