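"""Shared fixtures: small synthetic reference sets and surveys."""

from __future__ import annotations

import numpy as np
import pytest

from digestax import (GroupPlan, ReferenceSimSpec, SurveySimSpec,
                      simulate_reference_phylogeny, simulate_survey)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def small_refs():
    """16 species across 2 phyla, 1400 nt, rank-calibrated divergences."""
    return simulate_reference_phylogeny(ReferenceSimSpec(n_phyla=2, seed=42))


@pytest.fixture(scope="session")
def tiny_refs():
    """4 species in one family (2 genera x 2 species), 600 nt."""
    spec = ReferenceSimSpec(
        n_phyla=1,
        branching={"class": 1, "order": 1, "family": 1, "genus": 2,
                   "species": 2},
        length=600, seed=7)
    return simulate_reference_phylogeny(spec)


@pytest.fixture(scope="session")
def survey():
    """Two groups x 20 samples at depth 50,000 with planted categories."""
    spec = SurveySimSpec(
        groups=[GroupPlan("Wastewater sludge"), GroupPlan("Food waste")],
        depth=50_000, seed=11)
    return simulate_survey(spec)
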