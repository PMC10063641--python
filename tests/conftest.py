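import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bundled_models():
    from deltarad.signatures import load_bundled_models
    return load_bundled_models()


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-subject imaged cohort for I/O and integration tests."""
    from deltarad.synthetic import SimulationConfig, simulate_cohort
    return simulate_cohort(SimulationConfig(n_subjects=20, seed=101))


@pytest.fixture(scope="session")
def discovery_run():
    """One full discovery analysis (no survival CV) on a default cohort."""
    from deltarad.pipeline import (StudyParams, delta_feature_table,
                                   discover_phenotypes,
                                   extract_cohort_features)
    from deltarad.synthetic import SimulationConfig, simulate_cohort
    cohort = simulate_cohort(SimulationConfig(seed=42))
    params = StudyParams(seed=42)
    features, ftv2, dropped = extract_cohort_features(cohort, params)
    deltas, z, stats, qc = delta_feature_table(features, params)
    disc = discover_phenotypes(z, stats, params)
    return {"cohort": cohort, "params": params, "features": features,
            "ftv2": ftv2, "deltas": deltas, "z": z, "stats": stats,
            "qc": qc, **disc}


def toy_series(I0, I1, I2, times=(0.0, 2.5, 7.5), spacing=(1, 1, 1),
               mask=None):
    """Build a DceSeries from per-voxel intensity arrays."""
    from deltarad.kinetics import DceSeries
    I0, I1, I2 = (np.atleast_3d(np.asarray(v, dtype=float))
                  for v in (I0, I1, I2))
    if mask is None:
        mask = np.ones(I0.shape, dtype=bool)
    return DceSeries(volumes=np.stack([I0, I1, I2]), times=times,
                     spacing=spacing, mask=mask)
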