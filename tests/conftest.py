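import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_experiment():
    """A modest simulated run (5k droplets, 8 samples) with ground truth."""
    from hashdemux import LoadingModel, SignalModel, simulate_experiment

    loading = LoadingModel(n_droplets=5000)
    signal = SignalModel()
    matrix, truth = simulate_experiment(loading, signal, seed=42)
    return loading, signal, matrix, truth


@pytest.fixture(scope="session")
def fitted(small_experiment):
    """Fitted results for the small experiment (RNA-UMI gated)."""
    from hashdemux import CellHashingModel

    _, _, matrix, truth = small_experiment
    rna = pd.Series(
        truth.set_index("droplet_id").loc[matrix.barcodes, "rna_umi"].to_numpy(),
        index=matrix.barcodes,
    )
    model = CellHashingModel(matrix, rna_umi=rna)
    return model.fit(seed=42)


def truth_indexed(truth, index):
    return truth.set_index("droplet_id").loc[index]
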