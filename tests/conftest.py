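"""Shared fixtures: small synthetic genomes reused across the suite.

All fixtures are generated at desk scale (tens of kb per chromosome) with
fixed seeds; every test that checks a statistical property states its own
tolerance against the generator's ground truth.
"""

import pytest

from polyphase.simulate import (
    default_model,
    hexaploid_ab_spec,
    make_tully_fixture,
    plant_markers,
    simulate_ancestral_genomes,
)


@pytest.fixture(scope="session")
def tully_small():
    """48-chromosome aneuploid octoploid fixture (30 kb base chromosomes),
    with the default subgenome-specific repeat families."""
    polyploid, truth = make_tully_fixture(seed=3, length=30_000)
    return polyploid, truth


@pytest.fixture(scope="session")
def tully_with_markers():
    """Same composition, with 18 planted single-copy markers (own genome
    so marker truth does not leak into other fixtures)."""
    polyploid, truth = make_tully_fixture(seed=41, length=30_000)
    polyploid, markers = plant_markers(
        polyploid, truth, n_markers=18, marker_length=500, seed=5
    )
    return polyploid, markers, truth


@pytest.fixture(scope="session")
def hexaploid_small():
    """36-chromosome AABBBB fixture (20 kb base chromosomes, no repeats):
    the clean dosage substrate for read-composition tests."""
    polyploid, truth = make_tully_fixture(
        seed=31, length=20_000, families=False, spec=hexaploid_ab_spec()
    )
    return polyploid, truth


@pytest.fixture(scope="session")
def ancestral_default():
    """Ancestral A/B/C chromosome sets at the default divergences."""
    model = default_model(seed=1, length=50_000)
    return simulate_ancestral_genomes(model), model
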