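"""Shared fixtures: one desk-scale synthetic study reused across test modules."""

import warnings

import numpy as np
import pytest

import rilgp
from rilgp import simdata
from rilgp.phenotypes import entry_means_all_traits


@pytest.fixture(scope="session")
def small_config() -> rilgp.SimConfig:
    return rilgp.SimConfig(
        n_variants=800,
        n_transcripts=400,
        pop_sizes=(30, 30, 30),
        traits=(("t1", 4, 0.85), ("t2", 5, 0.80)),
        array_size=100,
        seed=7,
    )


@pytest.fixture(scope="session")
def sim(small_config) -> simdata.SimResult:
    return simdata.simulate_study(small_config)


@pytest.fixture(scope="session")
def entry_means(sim):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        means, summary = entry_means_all_traits(
            sim.phenotypes, lines=sim.popmap.ril_lines
        )
    return means, summary


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
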