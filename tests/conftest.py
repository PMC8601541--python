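import numpy as np
import pandas as pd
import pytest

import microbench as mb


@pytest.fixture(scope="session")
def small_template():
    """60-OTU diet (3) x dose (2) template with 4 samples per cell."""
    return mb.make_default_template(n_otus=60, n_per_cell=4, seed=1)


@pytest.fixture(scope="session")
def few_high_sim(small_template):
    """One simulated dataset with 5 strongly spiked OTUs on diet level A."""
    spec = mb.ScenarioSpec(n_da=5, log2fc_low=8.0, log2fc_high=9.0, seed=11)
    params, truth, fc = mb.apply_scenario(small_template, spec)
    return mb.sample_counts(params, seed=12, truth=truth, realized_log2fc=fc)


@pytest.fixture()
def toy_design_meta():
    """Balanced 3x2 metadata over 24 samples."""
    idx = [f"S{i:02d}" for i in range(24)]
    return pd.DataFrame(
        {"diet": (list("AAAA") + list("BBBB") + list("CCCC")) * 2,
         "dose": ["lo"] * 12 + ["hi"] * 12},
        index=idx,
    )


@pytest.fixture()
def toy_clr(toy_design_meta):
    """Row-centered Gaussian matrix mimicking clr output."""
    rng = np.random.default_rng(42)
    X = pd.DataFrame(
        rng.normal(size=(24, 15)),
        index=toy_design_meta.index,
        columns=[f"OTU{j}" for j in range(15)],
    )
    return X.sub(X.mean(axis=1), axis=0)
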