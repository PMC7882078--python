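from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirscreen.descreen import CONTROL, DISEASE, ExpressionStudy
from mirscreen.netbuild import RegulatoryNetwork
from mirscreen.synthdata import SynthConfig


def make_study(values: np.ndarray, n_disease: int, feature_ids=None) -> ExpressionStudy:
    """Wrap a matrix whose first n_disease columns are the disease group."""
    n_feat, n_samp = values.shape
    if feature_ids is None:
        feature_ids = [f"f{i:03d}" for i in range(n_feat)]
    cols = [f"s{i:03d}" for i in range(n_samp)]
    groups = pd.Series(
        [DISEASE] * n_disease + [CONTROL] * (n_samp - n_disease), index=cols
    )
    return ExpressionStudy(
        values=pd.DataFrame(values, index=feature_ids, columns=cols),
        sample_groups=groups,
    )


def random_bipartite(
    rng: np.random.Generator, n_mirnas: int, n_genes: int, density: float
) -> RegulatoryNetwork:
    edges = set()
    for i in range(n_mirnas):
        for j in range(n_genes):
            if rng.random() < density:
                edges.add((f"m{i:02d}", f"g{j:02d}"))
    # keep every miRNA present so per-node queries are well-defined
    for i in range(n_mirnas):
        if not any(m == f"m{i:02d}" for m, _ in edges):
            edges.add((f"m{i:02d}", f"g{int(rng.integers(n_genes)):02d}"))
    return RegulatoryNetwork.from_edges(edges)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """Scaled-down study conditions for fast end-to-end tests."""
    return SynthConfig(
        seed=11,
        n_mirnas=60,
        n_genes=500,
        n_tfs=40,
        background_edge_density=0.05,
        n_planted=5,
        planted_exclusive_targets=12,
        n_background_de_mirnas=40,
        n_background_de_genes=120,
        n_samples_per_group=12,
        n_mrna_studies=2,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    """Fresh deterministic generator per test, so runs are order-independent."""
    return np.random.default_rng(20240917)
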