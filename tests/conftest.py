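import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import slimscan as ss

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Fixed study seed used for the synthetic benchmark bundles.
STUDY_SEED = 20180712


@pytest.fixture(scope="session")
def benchmark_bundles():
    """Per-domain unbalanced bundles at the reference class sizes
    (115/140/165 positives, 120 background), strong planted signal."""
    return ss.generate_bundle(seed=STUDY_SEED, signal_strength=0.8)


@pytest.fixture(scope="session")
def sh3_bundle(benchmark_bundles):
    return benchmark_bundles["SH3"]


@pytest.fixture(scope="session")
def sh3_cv_results(sh3_bundle):
    """Five-fold CV of all four methods on the SH3 benchmark bundle,
    with SVM hyperparameters grid-selected on the same bundle."""
    grid = [(2.0**g, 2.0**c) for g in (-4, -2, 0) for c in (0, 2, 4)]
    scheme = ss.scheme_from_positives(
        ("AAC", "DPC", "TPC"), (e.sequence for e in sh3_bundle.positives)
    )
    gamma, C = ss.tune_hyperparameters(
        sh3_bundle, scheme, grid=grid, seed=STUDY_SEED
    )
    out = {}
    for method in ("SVM", "PSSM", "RES", "MIM"):
        config = ss.EvalConfig(gamma=gamma, C=C) if method == "SVM" else None
        out[method] = ss.cross_validate(
            sh3_bundle, method, config, seed=STUDY_SEED
        )
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_peptide(rng, length):
    from slimscan.alphabet import AMINO_ACIDS

    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
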