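import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tertbayes import LikelihoodSet, datasets

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_likelihoods() -> LikelihoodSet:
    """The rounded reference likelihoods {0.41, 0.59, 0.014, 0.986}."""
    return LikelihoodSet(0.41, 0.59, 0.014, 0.986)


@pytest.fixture(scope="session")
def uncertain_cohort() -> pd.DataFrame:
    """The packaged 175-lesion uncertain cohort table."""
    return datasets.uncertain_cohort()


def bayes_oracle(prior: float, s: float, f: float, positive: bool) -> float:
    """Brute-force Bayes: enumerate the four joint (state, result) outcomes.

    Builds the full joint distribution over {malignant, benign} x {+, -}
    from the prior and the per-state result probabilities, then normalises
    the malignant mass within the observed result column.  Independent of
    the package's algebraic form.
    """
    joint = {
        ("malignant", "+"): prior * s,
        ("malignant", "-"): prior * (1 - s),
        ("benign", "+"): (1 - prior) * f,
        ("benign", "-"): (1 - prior) * (1 - f),
    }
    result = "+" if positive else "-"
    column = {state: joint[(state, result)] for state in ("malignant", "benign")}
    total = sum(column.values())
    if total == 0:
        raise ZeroDivisionError("observed result has probability zero")
    return column["malignant"] / total
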