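import numpy as np
import pandas as pd
import pytest

from famgxe.simulate import BehaviorSimParams, simulate_phenotypes


def make_pheno(groups: dict[str, list[float]], exposure: str = "control") -> pd.DataFrame:
    """Phenotype table from a {family: values} mapping (single environment)."""
    rows = []
    for fam, values in groups.items():
        for i, v in enumerate(values):
            rows.append({"individual_id": f"{fam}_{i}", "family_id": fam,
                         "exposure": exposure, "value": float(v)})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def gxe_sim():
    """Moderate-interaction dataset on the 12-family nested design."""
    params = BehaviorSimParams(mu=100.0, alpha=5.0, sigma2_G=4.0,
                               sigma2_GxE=10.0, sigma2_E=20.0,
                               n_per_family=40, seed=3)
    return simulate_phenotypes(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
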