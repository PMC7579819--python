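"""Shared fixtures: small deterministic synthetic studies and graphs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from transnet.datatypes import (
    CausalGraph,
    ExpressionMatrix,
    GeneAnnotation,
    SnpPanel,
    TrueSystem,
)
from transnet.synthetic import simulate_cohorts, simulate_study, true_graph


@pytest.fixture(scope="session")
def default_study():
    """One default-scale synthetic study (30 genes, 300/cohort)."""
    return simulate_study(seed=11)


@pytest.fixture(scope="session")
def small_panel():
    return SnpPanel(pd.DataFrame({
        "snp_id": ["rs1", "rs2", "rs3"],
        "chrom": ["1", "1", "1"],
        "pos": [61_000, 90_000, 300_000],
        "maf": [0.3, 0.2, 0.5],
    }))


@pytest.fixture()
def chain_system():
    """g0 -> g1 -> g2 chain with effects 0.8 and -0.5, unit noise."""
    lam = np.zeros((3, 3))
    lam[1, 0] = 0.8
    lam[2, 1] = -0.5
    return TrueSystem(
        gene_ids=["G00", "G01", "G02"], lambda_true=lam,
        genetic_effects={}, sigma2=np.ones(3),
    )


def expression_for(system: TrueSystem, n: int, seed: int,
                   n_cases: int = 0) -> ExpressionMatrix:
    """Expression with no genotype contribution (empty genetic effects)."""
    dummy = pd.DataFrame({"none": np.zeros(n + n_cases)},
                         index=[f"S{i:04d}" for i in range(n + n_cases)])
    return simulate_cohorts(system, dummy, n_cases=n_cases, n_controls=n,
                            seed=seed)


@pytest.fixture()
def hand_dag():
    """A -> B, A -> C, B -> C, C -> D."""
    g = CausalGraph()
    for node in "ABCD":
        g.add_gene(node)
    for u, v in [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D")]:
        g.add_edge(u, v, effect=1.0, p=0.001)
    return g


@pytest.fixture()
def genes_single():
    return GeneAnnotation(pd.DataFrame({
        "gene_id": ["GX"], "chrom": ["1"], "tss": [100_000],
        "tes": [120_000], "strand": ["+"],
    }))
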