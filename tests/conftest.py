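import numpy as np
import pandas as pd
import pytest

from metaconc import GeneratorConfig, fixture_molecules, generate_table


@pytest.fixture(scope="session")
def fixtures_by_id():
    return {rec.id: rec for rec in fixture_molecules()}


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort shared by read-only tests."""
    cfg = GeneratorConfig(n_metabolites=60, n_conditions=3, seed=7)
    descriptors, datasets, truth = generate_table(cfg)
    return cfg, descriptors, datasets, truth


def make_table(x, y, parameter="NPSA"):
    """Minimal analysis table for the statistics layer."""
    x = np.asarray(x, dtype=float)
    return pd.DataFrame(
        {parameter: x, "log10_conc": np.asarray(y, dtype=float)},
        index=pd.Index([f"m{i}" for i in range(len(x))], name="id"),
    )
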