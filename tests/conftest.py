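"""Shared fixtures: one default simulated dataset and pipeline run per session."""
import numpy as np
import pandas as pd
import pytest

from methex import methylome
from methex.pipeline import build_matrix, run_pipeline
from methex.simulate import SimulationConfig, simulate_dataset

DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    return simulate_dataset(default_config)


@pytest.fixture(scope="session")
def default_matrix(default_dataset):
    return build_matrix(default_dataset)


@pytest.fixture(scope="session")
def pipeline_result(default_config):
    return run_pipeline(default_config)


@pytest.fixture()
def tiny_matrix_factory():
    """Build a MethylationMatrix from per-sample (chrom, pos, C, T) tuples."""

    def _make(samples: dict, design: pd.DataFrame | None = None,
              min_coverage: int = 1):
        singles = {}
        for name, rows in samples.items():
            df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])
            df["strand"] = "+"
            df["context"] = "CpG"
            df = df.rename(columns={"meth": "count_methylated",
                                    "unmeth": "count_unmethylated"})
            singles[name] = methylome.compute_levels(df, min_coverage=min_coverage)
        if design is None:
            design = pd.DataFrame(
                {"stage": ["p21"] * len(samples), "replicate": 1},
                index=pd.Index(list(samples), name="sample"))
        return methylome.merge_samples(singles, design)

    return _make


def make_two_group_design(n_per=3):
    samples = [f"p21_{i+1}" for i in range(n_per)] + \
              [f"p28_{i+1}" for i in range(n_per)]
    return pd.DataFrame(
        {"stage": ["p21"] * n_per + ["p28"] * n_per,
         "replicate": list(range(1, n_per + 1)) * 2},
        index=pd.Index(samples, name="sample"))
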