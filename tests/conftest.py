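import dataclasses

import pandas as pd
import pytest

from cernet import ExpressionMatrix, SampleSheet, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down cohort for fast unit tests (signals unchanged)."""
    return SimulationConfig(
        n_case=12, n_control=12, n_mrna=60, n_mirna=60, n_lncrna=60,
        n_cpg_genes=60, n_planted_de=8, n_planted_triads=2,
        n_planted_hypo_up=1, n_confounded=6, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture
def toy_matrix():
    def make(rows: dict[str, list[float]], layer: str = "mRNA",
             samples: list[str] | None = None) -> ExpressionMatrix:
        df = pd.DataFrame(rows).T
        df.columns = samples or [f"S{i + 1}" for i in range(df.shape[1])]
        return ExpressionMatrix(df.astype(float), layer)

    return make


@pytest.fixture
def two_group_sheet():
    def make(n_case: int, n_control: int) -> SampleSheet:
        ids = [f"S{i + 1}" for i in range(n_case + n_control)]
        return SampleSheet(pd.DataFrame({
            "sample_id": ids,
            "group": ["case"] * n_case + ["control"] * n_control,
        }))

    return make


@pytest.fixture
def null_config():
    """No planted signal at all: the global null."""
    return SimulationConfig(
        n_case=10, n_control=10, n_mrna=100, n_mirna=4, n_lncrna=4,
        n_cpg_genes=4, n_planted_de=0, n_planted_triads=0,
        n_planted_hypo_up=0, n_confounded=0,
    )


def reseed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return dataclasses.replace(config, seed=seed)
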