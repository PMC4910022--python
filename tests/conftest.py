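import matplotlib

matplotlib.use("Agg", force=True)

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def variant_cohort(tmp_path_factory):
    """One simulated 8-patient cohort with all artifact types planted."""
    from ith_niche.simulate_variants import VariantSimConfig, simulate_variant_tables

    out = tmp_path_factory.mktemp("variants")
    cfg = VariantSimConfig(seed=11, ref_length=40_000)
    return simulate_variant_tables(cfg, out)


@pytest.fixture(scope="session")
def cohort_reference(variant_cohort):
    from pyfaidx import Fasta

    return Fasta(str(variant_cohort.reference_fasta))
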