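import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", message=".*[Cc]onverg.*")


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One default synthetic dataset shared by read-only tests."""
    from cistrans.synthetic import default_config, generate_all

    return generate_all(default_config(seed=7))


@pytest.fixture(scope="session")
def pipeline_result():
    """One full end-to-end run shared by the pipeline and acceptance tests.

    Affinity testing uses 300 Monte-Carlo repetitions per pair here; the
    repetition count only tightens the p_mean summary, not the estimate's
    validity (each run is an unbiased importance-sampling estimate).
    """
    from cistrans.pipeline import run_pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(seed=11, n_affinity_runs=300)


def simulate_gene(seed, log2fc, n_donors=24, per_donor=200, donor_sd=0.2, base=0.0):
    """One gene's counts under the hurdle-test study design: negative
    binomial around a donor-intercept mean, disease effect in half the
    donors."""
    rng = np.random.default_rng(seed)
    donor = np.repeat(np.arange(n_donors), per_donor)
    diag = (donor < n_donors // 2).astype(int)
    delta = rng.normal(0, donor_sd, n_donors)
    mu = 2.0 ** (base + delta[donor] + log2fc * diag)
    counts = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
    return counts, diag, donor
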