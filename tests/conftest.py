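"""Shared fixtures: small ground-truth models and a calibrated family model.

The session-scoped family model is built once from a synthetic enzyme
family (30 homologs of length 250 at 20% divergence) and calibrated on
2,000 background peptides; several end-to-end tests share it.
"""

import numpy as np
import pytest

from hmmscreen import profile_build as pb
from hmmscreen import search_engine as se
from hmmscreen import synthetic_data as sd


def random_small_model(rng: np.random.Generator, M: int) -> pb.ProfileHMM:
    """A random, fully valid profile for oracle comparisons."""
    match_emit = rng.dirichlet(np.ones(20) * 0.5, size=M)
    insert_emit = rng.dirichlet(np.ones(20), size=M + 1)
    transitions = np.zeros((M + 1, 7))
    transitions[:, 0:3] = rng.dirichlet(np.ones(3), size=M + 1)
    transitions[:, 3:5] = rng.dirichlet(np.ones(2), size=M + 1)
    transitions[:, 5:7] = rng.dirichlet(np.ones(2), size=M + 1)
    background = rng.dirichlet(np.ones(20) * 5)
    return pb.ProfileHMM(
        name="random",
        match_emit=match_emit,
        insert_emit=insert_emit,
        transitions=transitions,
        background=background,
    )


@pytest.fixture(scope="session")
def toy_model() -> pb.ProfileHMM:
    return sd.random_profile(10, seed=5)


@pytest.fixture(scope="session")
def family_setup():
    """(ancestor, family, calibrated model) for end-to-end screens."""
    ancestor, family = sd.make_family(length=250, n=30, divergence=0.2, seed=41)
    model = pb.build_profile(sd.family_alignment(family), name="family")
    se.calibrate(model, n_random=2000, length_dist=(100.0, 3.0), seed=42)
    return ancestor, family, model
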