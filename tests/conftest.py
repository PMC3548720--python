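import numpy as np
import pandas as pd
import pytest

import hypertabph as ht


@pytest.fixture(scope="session")
def unit_params():
    """alpha = beta = 1, the setting with hand-checkable closed forms."""
    return ht.HypertabasticParams(1.0, 1.0)


@pytest.fixture(scope="session")
def study_params():
    """Baseline shape estimates of the published four-covariate model."""
    return ht.HypertabasticParams(0.7247, 0.6205)


@pytest.fixture(scope="session")
def study_spec(study_params):
    """Published combined model: baseline plus the four coefficients."""
    return ht.PHModelSpec(
        family="hypertabastic",
        baseline_params=(study_params.alpha, study_params.beta),
        coefficients={"AGE": -0.0735, "70G": 1.199, "CSR": 2.661, "CERBB": 1.561},
    )


@pytest.fixture(scope="session")
def median_profile():
    """A plausible cohort-median covariate profile (poor prognosis)."""
    return {"AGE": 44.0, "70G": 1.0, "CSR": 0.0, "CERBB": 0.0}


@pytest.fixture(scope="session")
def synth_cohort():
    """A mid-sized synthetic cohort from the default truth (fixed seed)."""
    return ht.generate_cohort(ht.CohortConfig(n=800, seed=42))


@pytest.fixture(scope="session")
def synth_fit(synth_cohort):
    """Hypertabastic PH fit of the synthetic cohort (session-cached)."""
    result = ht.fit_ph(synth_cohort)
    assert result.converged
    return result


@pytest.fixture()
def small_table(tmp_path):
    """A well-formed 3-subject survival CSV on disk."""
    path = tmp_path / "tiny.csv"
    pd.DataFrame(
        {
            "time": [1.5, 4.0, 9.2],
            "event": [1, 0, 1],
            "AGE": [40.0, 50.0, 60.0],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120904)
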