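from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from poma.io import CASE, CONTROL, ExpressionMatrix, GeneSet, InteractionSet
from poma.pipeline import PipelineConfig
from poma.simulate import simulate_study


def interaction_set(pairs) -> InteractionSet:
    """Build an InteractionSet from bare (mirna, gene) pairs."""
    pairs = sorted(set(pairs))
    return InteractionSet(
        pd.DataFrame(
            {
                "mirna": [m for m, _ in pairs],
                "gene": [g for _, g in pairs],
                "sources": [frozenset(["test"])] * len(pairs),
            }
        )
    )


def random_bipartite_pairs(rng, n_mirna=20, n_gene=60, n_edges=80):
    mirnas = [f"miR-{i}" for i in range(n_mirna)]
    genes = [f"G{i}" for i in range(n_gene)]
    pairs = set()
    while len(pairs) < n_edges:
        pairs.add((mirnas[rng.integers(n_mirna)], genes[rng.integers(n_gene)]))
    return pairs


def two_group_matrix(values: dict[str, list[float]], n_case: int) -> ExpressionMatrix:
    """Small matrix from {gene: row}; first n_case columns are cases."""
    n = len(next(iter(values.values())))
    samples = [f"s{i}" for i in range(n)]
    groups = pd.Series(
        [CASE] * n_case + [CONTROL] * (n - n_case), index=samples, dtype=object
    )
    return ExpressionMatrix(pd.DataFrame(values, index=samples).T, groups)


@pytest.fixture(scope="session")
def toy_study(tmp_path_factory) -> dict[str, Path]:
    return simulate_study("toy", 0, tmp_path_factory.mktemp("toy"))


@pytest.fixture(scope="session")
def default_study(tmp_path_factory) -> dict[str, Path]:
    return simulate_study("default", 1, tmp_path_factory.mktemp("default"))


def study_config(paths: dict[str, Path], outdir: Path, **overrides) -> PipelineConfig:
    kwargs = dict(
        expression=paths["expression"],
        annotation=paths["annotation"],
        interactions=[paths["interactions_validated"], paths["interactions_predicted"]],
        tf_genes=paths["tf_genes"],
        disease_genes=paths["disease_genes"],
        associated_mirnas=paths["associated_mirnas"],
        outdir=outdir,
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)
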