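from pathlib import Path

import pandas as pd
import pytest

from metallomap.datamodel import build_presence_matrix, filter_proteins
from metallomap.gmpa import score_all
from metallomap.pipeline import ClusteringParams, RunConfig
from metallomap.synth import SynthConfig, generate

GOLDEN = Path(__file__).parent / "data" / "golden"


@pytest.fixture(scope="session")
def default_synth():
    """Default synthetic experiment, seed 1, shared across tests."""
    return generate(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_scores(default_synth):
    """(presence matrix, GMPA score table) for the default experiment."""
    exp = default_synth.experiment
    obs = filter_proteins(exp.observations)
    matrix = build_presence_matrix(obs, exp.fractions)
    return matrix, score_all(matrix, default_synth.peaksets)


@pytest.fixture()
def tiny_fractions():
    """One separation of 20 ordered fractions."""
    return pd.DataFrame(
        {
            "fraction_id": [f"F{k:02d}" for k in range(20)],
            "separation_id": "S01",
            "order_index": range(20),
            "parent_fraction_id": ".",
            "level": 1,
        }
    )


def golden_run_config(outdir: Path) -> RunConfig:
    """The pipeline configuration the golden outputs were produced with."""
    inp = GOLDEN / "inputs"
    return RunConfig(
        fractions=str(inp / "fractions.tsv"),
        metals=str(inp / "metals.tsv"),
        observations=str(inp / "observations.tsv"),
        peaks=str(inp / "peaks.tsv"),
        references=str(inp / "truth.tsv"),
        outdir=str(outdir),
        min_occurrences=3,
        clustering=ClusteringParams(min_cluster_size=2),
    )
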