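import numpy as np
import pytest

from rpntcp import SyntheticConfig, generate, registry


@pytest.fixture(scope="session")
def reg():
    return registry()


@pytest.fixture(scope="session")
def dev_cohort():
    """Development-style synthetic cohort (truth: tuned Model D)."""
    return generate(SyntheticConfig(n=2000, seed=101))


@pytest.fixture(scope="session")
def appelt_cohort():
    """Synthetic cohort whose outcomes come from the (tuned) Appelt model."""
    return generate(SyntheticConfig(n=2000, seed=202, true_model_name="appelt_original"))


@pytest.fixture()
def cohort_csv(tmp_path, dev_cohort):
    path = tmp_path / "cohort.csv"
    dev_cohort.to_csv(path)
    return path


def redraw_outcomes(cohort, probs, rng):
    """Fresh outcome draw on fixed covariates (fast replicate machinery)."""
    df = cohort.df.copy()
    df["event"] = (rng.uniform(size=len(df)) < probs).astype(int)
    df["rp_grade"] = np.where(df["event"] == 1, 2, 0)
    return cohort.with_df(df)
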