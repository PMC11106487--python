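import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from nanodomain import (  # noqa: E402
    BlinkModel,
    ClusterGroundTruth,
    RoiGeometry,
    compute_pair_correlation,
    simulate_localizations_clustered,
    simulate_localizations_random,
)


@pytest.fixture(scope="session")
def roi4um() -> RoiGeometry:
    return RoiGeometry(4000.0, 4000.0)


@pytest.fixture(scope="session")
def default_blink() -> BlinkModel:
    return BlinkModel(mean_localizations=3.0, sigma_s_nm=20.0)


@pytest.fixture(scope="session")
def clustered_truth() -> ClusterGroundTruth:
    """Ground truth at the default 67-nm domain diameter (xi = 33.5 nm)."""
    return ClusterGroundTruth(xi_nm=33.5, amplitude=5.0, density_per_um2=600.0)


@pytest.fixture(scope="session")
def csr_curves(roi4um, default_blink):
    """Eight pair-correlation curves from isolated-molecule (CSR) ROIs."""
    return [
        compute_pair_correlation(
            simulate_localizations_random(roi4um, 600.0, default_blink, seed=500 + s).table
        )
        for s in range(8)
    ]


@pytest.fixture(scope="session")
def pooled_sigma(csr_curves):
    """Condition-level sigma_s pooled from Eq.-1-type fits to CSR reference ROIs."""
    from nanodomain import fit_random_model

    return float(np.mean([fit_random_model(c).sigma_s_nm for c in csr_curves]))


@pytest.fixture(scope="session")
def clustered_curves(roi4um, default_blink, clustered_truth):
    """Twelve clustered-condition curves at the default ground truth."""
    return [
        compute_pair_correlation(
            simulate_localizations_clustered(
                roi4um, clustered_truth, default_blink, seed=100 + s
            ).table
        )
        for s in range(12)
    ]
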