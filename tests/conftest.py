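"""Shared fixtures: small simulated datasets reused across test modules.

Everything is generated programmatically at test time from fixed seeds;
no data files are stored.
"""

from __future__ import annotations

import numpy as np
import pytest

import hgtscreen as hs


@pytest.fixture(scope="session")
def small_scenario():
    """12-family scenario (10 vertical + 2 injected transfers)."""
    return hs.default_scenario(seed=11, n_vertical=10, n_hgt=2)


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    return hs.simulate_dataset(small_scenario)


@pytest.fixture(scope="session")
def small_screen(small_dataset):
    """Screen report for the small dataset (shared; read-only)."""
    inputs = hs.ScreenInputs(
        transcripts=small_dataset.parasite_transcripts,
        host_sets=small_dataset.host_cds,
        outgroup_sets=small_dataset.outgroup_cds,
        host_species_tree=small_dataset.host_species_tree(),
        homolog_coords=small_dataset.coords,
    )
    config = hs.PipelineConfig(bootstrap_reps=50, seed=11)
    return hs.run_screen(inputs, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_sense_codons(rng, n):
    """Random gap-free coding sequence of n sense codons."""
    from hgtscreen._codon import CODONS, SENSE

    idx = rng.integers(0, len(SENSE), size=n)
    return "".join(CODONS[SENSE[i]] for i in idx)
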