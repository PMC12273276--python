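import numpy as np
import pandas as pd
import pytest

from methclass import MethylationClassModel, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The reference synthetic cohort (default config, seed 1)."""
    cfg = SimulationConfig()
    beta, expr, sheet, truth = simulate_cohort(cfg, seed=1)
    return {"config": cfg, "beta": beta, "expr": expr, "sheet": sheet, "truth": truth}


@pytest.fixture(scope="session")
def fitted(default_cohort):
    """Methylation classes fitted on the reference cohort."""
    res = MethylationClassModel(default_cohort["beta"]).fit(
        k_range=range(2, 7), n_resamples=200, seed=1
    )
    return res


def tiny_sim_config(**overrides) -> SimulationConfig:
    """A fast, structurally complete simulation config for small tests."""
    base = dict(
        n_samples=40,
        n_sites=400,
        n_informative_sites=80,
        n_coupled_genes=20,
        n_genes=200,
        n_immune_genes=20,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture()
def tiny_cohort():
    cfg = tiny_sim_config()
    beta, expr, sheet, truth = simulate_cohort(cfg, seed=7)
    return {"config": cfg, "beta": beta, "expr": expr, "sheet": sheet, "truth": truth}


@pytest.fixture()
def toy_beta():
    """10 sites x 6 samples with known variances, no missing values."""
    rng = np.random.default_rng(42)
    vals = rng.uniform(0, 1, size=(10, 6))
    return pd.DataFrame(
        vals,
        index=[f"chr1:{100 * (i + 1)}" for i in range(10)],
        columns=[f"S{j}" for j in range(6)],
    )
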