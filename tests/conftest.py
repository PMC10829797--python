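import numpy as np
import pandas as pd
import pytest

from proteosubtype import nmf, preprocess
from proteosubtype.synthetic import SyntheticConfig, generate_cohort
from proteosubtype.types import OmicsMatrix


def make_matrix(values, features=None, samples=None, modality="protein"):
    values = np.asarray(values, dtype=float)
    f = features or [f"F{i + 1}" for i in range(values.shape[0])]
    s = samples or [f"S{i + 1}" for i in range(values.shape[1])]
    return OmicsMatrix(pd.DataFrame(values, index=f, columns=s), modality)


@pytest.fixture(scope="session")
def small_cohort():
    """60 samples, 3 subtypes, 40 features per modality: fast fixture."""
    cfg = SyntheticConfig(
        n_samples=60,
        k_true=3,
        n_features={"mrna": 40, "protein": 40, "phospho": 40},
        n_plexes=4,
        mutation_rates={"FLT3_ITD": [0.1, 0.6, 0.2], "NPM1": [0.1, 0.1, 0.5]},
        survival_hazards=[1.0, 2.0, 0.5],
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort under the default study conditions (n=160, k=4)."""
    return generate_cohort(SyntheticConfig(seed=11))


def preprocess_cohort(cohort):
    """Standard correction path: missingness filter, KNN impute, EB correct."""
    out = {}
    for mod, m in cohort.omics.items():
        m = preprocess.filter_missingness(m, 0.5)
        m = preprocess.knn_impute(m, k=10)
        m = preprocess.eb_covariate_correction(
            m, cohort.annotation, ["loading_mass", "plex"]
        )
        out[mod] = m
    return out


@pytest.fixture(scope="session")
def corrected_small(small_cohort):
    return preprocess_cohort(small_cohort)


@pytest.fixture(scope="session")
def small_split(corrected_small):
    return nmf.standardize_and_split(list(corrected_small.values()))


@pytest.fixture(scope="session")
def small_labels(small_split):
    """Consensus subtype labels for the small cohort at its true k."""
    return nmf.consensus_cluster(
        small_split, 3, n_runs=10, seed=0, max_iter=150, tol=1e-4
    ).labels


@pytest.fixture(scope="session")
def protein_phospho_small(corrected_small):
    both = pd.concat(
        [corrected_small["protein"].values, corrected_small["phospho"].values]
    )
    return OmicsMatrix(both, "protein+phospho")
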