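import pandas as pd
import pytest

from plasmaflux import (
    IntensityMatrix,
    SyntheticMetabolomeConfig,
    generate_intensity_matrix,
    load_default_network,
)


@pytest.fixture(scope="session")
def default_network():
    return load_default_network()


@pytest.fixture(scope="session")
def plasma_measurements():
    """Physiologically ordered plasma concentrations (umol/mL)."""
    return {"glc": 5.0, "lac": 2.0, "bhb": 0.3, "nadh": 0.05}


@pytest.fixture(scope="session")
def separable_matrix():
    """Strongly separated two-group matrix: many informative metabolites,
    tiny within-group noise — an OPLS-DA should model it near-perfectly."""
    cfg = SyntheticMetabolomeConfig(
        n_per_group=6,
        n_metabolites=60,
        frac_differential=0.5,
        effect_log2=4.0,
        base_log_sd=0.4,
        missing_rate=0.0,
        seed=42,
    )
    matrix, truth = generate_intensity_matrix(cfg)
    return matrix, truth


@pytest.fixture(scope="session")
def null_matrix():
    """No planted effects, no missingness."""
    cfg = SyntheticMetabolomeConfig(
        n_per_group=6, n_metabolites=60, frac_differential=0.0,
        missing_rate=0.0, seed=7,
    )
    matrix, _ = generate_intensity_matrix(cfg)
    return matrix


def toy_matrix(values, groups, classes=None, group_order=("low", "high")):
    """Small IntensityMatrix builder for hand fixtures."""
    values = pd.DataFrame(values)
    values.index = [f"s{i}" for i in range(values.shape[0])]
    values.columns = [f"M{j}" for j in range(values.shape[1])]
    expand = {"l": "low", "h": "high"}
    groups = pd.Series([expand.get(g, g) for g in groups], index=values.index)
    if classes is None:
        classes = pd.Series("other", index=values.columns)
    else:
        classes = pd.Series(list(classes), index=values.columns)
    return IntensityMatrix(values, groups, classes, group_order)


@pytest.fixture
def toy_builder():
    return toy_matrix
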