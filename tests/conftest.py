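import numpy as np
import pytest

from ucoseq import simdata
from ucoseq.core_io import CountMatrix, SampleTable


@pytest.fixture(scope="session")
def small_config():
    """Compact synthetic experiment: full design, reduced gene space."""
    return simdata.SimulationConfig(
        seed=11,
        n_genes=800,
        markers_per_type=5,
        n_trend_genes=10,
        n_injury_genes=6,
        fraction_shift=1.0,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simdata.simulate_experiment(small_config)


@pytest.fixture(scope="session")
def null_experiment():
    """No planted signal anywhere: the calibration backbone."""
    cfg = simdata.SimulationConfig(
        seed=17,
        n_genes=600,
        markers_per_type=5,
        n_trend_genes=0,
        n_injury_genes=0,
        fraction_shift=0.0,
    )
    return simdata.simulate_experiment(cfg)


@pytest.fixture()
def toy_counts():
    rng = np.random.default_rng(3)
    values = rng.negative_binomial(5, 0.01, size=(40, 6))
    return CountMatrix(values, [f"g{i}" for i in range(40)], [f"s{j}" for j in range(6)])


def make_sample_table(n_animals=4, timepoints=(-1.0, 6.0, 24.0)):
    rows = []
    for i in range(n_animals):
        for tp in timepoints:
            rows.append(
                {
                    "sample_id": f"A{i}_{tp:g}",
                    "animal_id": f"A{i}",
                    "timepoint_h": tp,
                    "treatment": "vehicle" if i % 2 else "active",
                    "phase": "pre" if tp < 0 else "post",
                    "injury_class": "mild" if i % 2 else "severe",
                }
            )
    import pandas as pd

    return SampleTable(pd.DataFrame(rows))
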