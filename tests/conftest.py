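"""Shared fixtures.

Heavy session-scoped fixtures (trained tiny language models and their
simulated corpora) are shared between the acceptance tests so each model is
trained exactly once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from vhhlm.lm import MaskedLanguageModel
from vhhlm.simulate import (Cdr3Config, ShmConfig, default_property_model,
                            simulate_property, simulate_repertoire,
                            species_scaffolds)


@pytest.fixture(scope="session")
def scaffolds_a():
    return species_scaffolds("vhh")


@pytest.fixture(scope="session")
def scaffolds_b():
    return species_scaffolds("human")


@pytest.fixture(scope="session")
def small_repertoire(scaffolds_a):
    """200 species-A sequences at default SHM settings."""
    return simulate_repertoire(scaffolds_a, ShmConfig(seed=1), Cdr3Config(seed=1),
                               200, seed=11, species="vhh")


# ---------------------------------------------------------------------------
# trained models (session-scoped; built on first use)
# ---------------------------------------------------------------------------

SPECIES_TRAIN_N = 6000
SPECIES_HELD_N = 100


def _species_corpus(species, shm_seed, sim_seed):
    scaffolds = species_scaffolds(species)
    recs = simulate_repertoire(scaffolds, ShmConfig(seed=shm_seed),
                               Cdr3Config(seed=shm_seed),
                               SPECIES_TRAIN_N + SPECIES_HELD_N,
                               seed=sim_seed, species=species)
    return recs[:SPECIES_TRAIN_N], recs[SPECIES_TRAIN_N:]


@pytest.fixture(scope="session")
def corpus_a():
    return _species_corpus("vhh", shm_seed=1, sim_seed=41)


@pytest.fixture(scope="session")
def corpus_b():
    return _species_corpus("human", shm_seed=2, sim_seed=42)


@pytest.fixture(scope="session")
def model_a(corpus_a):
    train, _ = corpus_a
    return MaskedLanguageModel(n_epochs=3, random_state=3).fit(train)


@pytest.fixture(scope="session")
def model_b(corpus_b):
    train, _ = corpus_b
    return MaskedLanguageModel(n_epochs=3, random_state=4).fit(train)


@pytest.fixture(scope="session")
def thermo_records(scaffolds_a):
    """400 species-A records with simulated melting temperatures."""
    recs = simulate_repertoire(scaffolds_a, ShmConfig(seed=5), Cdr3Config(seed=5),
                               400, seed=43, species="vhh")
    simulate_property(recs, default_property_model(seed=44, noise_sd=1.5),
                      scaffolds_a)
    return recs
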