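"""Shared fixtures: small trees, a synthetic study, and the published
life-history AICc table used for arithmetic cross-checks."""

import numpy as np
import pytest

import pglspath as pp

# Published comparison of 25 candidate life-history models of aggression
# intensity (57-species dataset): predictor abbreviations CS clutch size,
# PR provisioning rate, FM feeding method, BM body mass, NP nestling period,
# with the printed AICc value per model.
PUBLISHED_LH_MODELS = {
    ("CS", "PR", "FM"): 145.91,
    ("CS", "PR", "FM", "NP"): 146.20,
    ("CS", "PR", "FM", "BM"): 148.09,
    ("CS", "PR"): 148.77,
    ("CS", "FM"): 150.02,
    ("PR", "FM"): 150.24,
    ("CS", "PR", "NP"): 150.38,
    ("CS", "PR", "BM"): 151.18,
    ("PR",): 151.35,
    ("CS", "FM", "BM"): 152.24,
    ("CS", "FM", "NP"): 152.37,
    ("PR", "FM", "BM"): 152.55,
    ("PR", "FM", "NP"): 152.64,
    ("CS",): 152.75,
    ("PR", "BM"): 153.23,
    ("PR", "NP"): 153.58,
    ("CS", "BM"): 154.18,
    ("CS", "NP"): 155.01,
    ("NP",): 160.96,
    ("BM",): 161.01,
    ("NP", "FM"): 161.57,
    ("BM", "FM"): 162.12,
    ("NP", "BM"): 162.88,
    (): 164.40,
    ("FM",): 164.72,
}

# Relative likelihoods of the 21 truly competing path models as published
# (ordered by CICc; the top model's recalculated weight is 1 / sum).
PUBLISHED_PATH_REL_LIKELIHOODS = [
    1.000, 0.717, 0.600, 0.498, 0.498, 0.498, 0.415, 0.357, 0.357, 0.357,
    0.299, 0.299, 0.299, 0.298, 0.236, 0.207, 0.207, 0.207, 0.148, 0.148, 0.148,
]


def published_candidates():
    """CandidateModel list built from the published AICc table."""
    from pglspath.model_selection import CandidateModel

    return [
        CandidateModel(predictors=preds, aicc=a, K=len(preds) + 2)
        for preds, a in PUBLISHED_LH_MODELS.items()
    ]


@pytest.fixture(scope="session")
def three_tip_tree():
    return pp.parse_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture(scope="session")
def study_fixture():
    """One default synthetic study (65 species), shared across tests."""
    return pp.build_study_fixture(pp.SyntheticStudyConfig(seed=11))


@pytest.fixture(scope="session")
def small_tree():
    return pp.simulate_tree(40, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
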