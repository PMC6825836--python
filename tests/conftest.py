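import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from binmi.datamodel import CovariateTable, Variable
from binmi.synthetic_data import CohortSpec, EffectSpec, generate_cohort, generate_methylation


@pytest.fixture(scope="session")
def cohort464():
    """Reference-size cohort (464 individuals), fully observed."""
    return generate_cohort(CohortSpec(n_individuals=464), seed=101)


@pytest.fixture(scope="session")
def meth500(cohort464):
    """500 standardized sites, 20 with planted smoking effects."""
    return generate_methylation(cohort464, EffectSpec(n_sites=500, n_true=20), seed=102)


def make_covariates(age, sex, smoking, extra=None):
    """Small helper to build a CovariateTable from raw arrays."""
    n = len(age)
    data = {"age": np.asarray(age, float), "sex": np.asarray(sex, float), "smoking": smoking}
    schema = {
        "age": Variable("age", "continuous"),
        "sex": Variable("sex", "binary"),
        "smoking": Variable(
            "smoking", "categorical", levels=("never", "former", "current"), reference="never"
        ),
    }
    if extra:
        for name, (values, var) in extra.items():
            data[name] = values
            schema[name] = var
    df = pd.DataFrame(data, index=pd.Index([f"s{i:04d}" for i in range(n)], name="sample_id"))
    return CovariateTable(df, schema)
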