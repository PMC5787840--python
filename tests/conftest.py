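import numpy as np
import pandas as pd
import pytest

from droughtdex import SimConfig, simulate_experiment, simulate_orthogonal


@pytest.fixture(scope="session")
def small_experiment():
    """A small two-pair experiment with planted responsive and stable genes."""
    cfg = SimConfig(n_genes=400, n_responsive=15, n_stable=6, seed=42)
    matrix, tmap, design, truth = simulate_experiment(cfg)
    return cfg, matrix, tmap, design, truth


@pytest.fixture(scope="session")
def small_orthogonal(small_experiment):
    _, _, _, _, truth = small_experiment
    return simulate_orthogonal(truth, concordance_rate=1.0, seed=42)


@pytest.fixture
def de_table_factory():
    """Build a DE table from per-gene (mean_a, mean_b, log2fc, p, q) tuples."""

    def make(rows: dict[str, tuple]) -> pd.DataFrame:
        frame = pd.DataFrame.from_dict(
            rows, orient="index", columns=["mean_a", "mean_b", "log2fc", "p_value", "q_value"]
        )
        frame.index.name = "gene_id"
        frame["direction"] = np.where(
            frame["q_value"] < 0.05,
            np.where(frame["log2fc"] > 0, "up", "down"),
            "none",
        )
        return frame

    return make
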