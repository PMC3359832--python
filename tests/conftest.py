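import numpy as np
import pandas as pd
import pytest

from pbsc.containers import ExpressionMatrix, PathwayCollection, ReferenceBank, ReferenceInstance
from pbsc.simulate import SimulationConfig


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 2 paired samples on log2 scale."""
    df = pd.DataFrame(
        {"s_pre": [1.0, 2.0, 3.0], "s_post": [3.0, 2.0, 1.0]},
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    return ExpressionMatrix(df, pair_map={"pA": ("s_pre", "s_post")})


@pytest.fixture
def small_pathways() -> PathwayCollection:
    return PathwayCollection(
        {
            "pwA": frozenset({"g1", "g2"}),
            "pwB": frozenset({"g2", "g3", "g4"}),
        }
    )


def make_instance(instance_id: str, order, compound="drug", dose="1 uM") -> ReferenceInstance:
    return ReferenceInstance(
        instance_id=instance_id,
        compound=compound,
        dose=dose,
        cell_line="",
        order=np.asarray(order, dtype=object),
    )


@pytest.fixture
def two_instance_bank() -> ReferenceBank:
    genes = ["g1", "g2", "g3", "g4"]
    return ReferenceBank(
        [
            make_instance("i1", genes),
            make_instance("i2", genes[::-1], compound="other"),
        ]
    )


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    """Scaled-down scenario for fast unit tests."""
    return SimulationConfig(
        n_genes=400,
        n_instances=8,
        n_pathways=20,
        pathway_size_range=(10, 40),
        signature_size=15,
        affected_pathways_per_instance=3,
        seed=7,
    )
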