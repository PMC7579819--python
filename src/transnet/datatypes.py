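"""Core containers shared across the pipeline.

Conventions used throughout:

* SNP positions are 1-based basepairs (VCF convention).
* Hi-C anchors and BED-like intervals are 0-based half-open.
* Gene cis windows are inclusive on both ends: ``[tss - window, tes + window]``.
* Expression matrices are samples x genes; genotype matrices samples x SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

GENE_NODE = "gene"
IV_NODE = "iv"


@dataclass
class SnpPanel:
    """SNP identifiers with genomic coordinates and minor-allele frequencies.

    ``table`` columns: snp_id, chrom, pos (1-based), maf. Positions must be
    strictly increasing within each chromosome and mafs in (0, 0.5].
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos", "maf"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"SnpPanel table missing columns: {sorted(missing)}")
        maf = self.table["maf"].to_numpy(float)
        if np.any((maf <= 0) | (maf > 0.5)):
            raise ValueError("maf must lie in (0, 0.5]")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"SNP positions not strictly increasing on {chrom}")
        if self.table["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in panel")

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneAnnotation:
    """BED-like gene annotation: gene_id, chrom, tss, tes, strand.

    tss <= tes in genomic coordinates (already normalized; strand is carried
    but windows are strand-symmetric).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "tss", "tes", "strand"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"GeneAnnotation missing columns: {sorted(missing)}")
        if (self.table["tss"] > self.table["tes"]).any():
            raise ValueError("tss must be <= tes (genomic coordinates)")
        if self.table["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id")

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def row(self, gene_id: str) -> pd.Series:
        sub = self.table[self.table["gene_id"] == gene_id]
        if sub.empty:
            raise KeyError(gene_id)
        return sub.iloc[0]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class HiCContactMap:
    """Deduplicated unordered anchor pairs; anchors 0-based half-open.

    ``table`` columns: chrom_a, start_a, end_a, chrom_b, start_b, end_b.
    """

    table: pd.DataFrame

    COLUMNS = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"]

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"HiCContactMap missing columns: {sorted(missing)}")
        t = self.table
        if ((t["start_a"] >= t["end_a"]) | (t["start_b"] >= t["end_b"])).any():
            raise ValueError("anchor start must be < end")

    @staticmethod
    def from_records(records: list[tuple]) -> "HiCContactMap":
        """Build from (chrom_a, start_a, end_a, chrom_b, start_b, end_b) tuples,
        deduplicating as unordered pairs."""
        seen = set()
        rows = []
        for rec in records:
            a, b = tuple(rec[:3]), tuple(rec[3:6])
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            rows.append(rec)
        return HiCContactMap(pd.DataFrame(rows, columns=HiCContactMap.COLUMNS))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TrueSystem:
    """Ground-truth recursive linear system over genes.

    lambda_true[i, j] is the effect of gene j on gene i; strictly lower
    triangular in the generating order, hence acyclic. ``deleted_edges_cases``
    holds (mediator, downstream) gene-id pairs zeroed in the case cohort —
    the "loss of mediator" mechanism.
    """

    gene_ids: list[str]
    lambda_true: np.ndarray
    genetic_effects: dict[str, tuple[str, float]]  # snp_id -> (gene_id, effect)
    sigma2: np.ndarray
    deleted_edges_cases: set[tuple[str, str]] = field(default_factory=set)
    covariate_loadings: np.ndarray | None = None  # genes x covariates

    def __post_init__(self) -> None:
        p = len(self.gene_ids)
        lam = np.asarray(self.lambda_true, float)
        if lam.shape != (p, p):
            raise ValueError("lambda_true shape mismatch")
        if np.any(np.triu(lam) != 0):
            raise ValueError("lambda_true must be strictly lower triangular")
        if np.any(np.asarray(self.sigma2) <= 0):
            raise ValueError("residual variances must be positive")
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        for m, d in self.deleted_edges_cases:
            if lam[idx[d], idx[m]] == 0:
                raise ValueError(f"deleted edge ({m}->{d}) absent from lambda_true")
        self.lambda_true = lam

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def true_edges(self) -> set[tuple[str, str]]:
        """(source, target) pairs with nonzero effect."""
        rows, cols = np.nonzero(self.lambda_true)
        return {(self.gene_ids[j], self.gene_ids[i]) for i, j in zip(rows, cols)}

    def lambda_cases(self) -> np.ndarray:
        lam = self.lambda_true.copy()
        idx = self.index
        for m, d in self.deleted_edges_cases:
            lam[idx[d], idx[m]] = 0.0
        return lam


@dataclass
class ExpressionMatrix:
    """Samples x genes expression with a per-sample cohort label."""

    values: pd.DataFrame
    cohort: pd.Series  # 'case' / 'control', indexed by sample
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression contains missing values")
        if not self.cohort.index.equals(self.values.index):
            self.cohort = self.cohort.reindex(self.values.index)
            if self.cohort.isna().any():
                raise ValueError("cohort label missing for some samples")

    @property
    def samples(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def gene_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def subset(self, cohort: str) -> "ExpressionMatrix":
        mask = self.cohort == cohort
        cov = self.covariates.loc[mask] if self.covariates is not None else None
        return ExpressionMatrix(self.values.loc[mask], self.cohort.loc[mask], cov)


@dataclass
class RegionSnpSet:
    """SNPs assigned to one gene's regulatory region with provenance."""

    gene_id: str
    snp_ids: list[str]
    provenance: dict[str, str]  # snp_id -> 'cis' | 'hic'

    def __post_init__(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp_ids in region set")

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class CaDecomposition:
    """Correspondence-analysis decomposition of a genotype indicator table.

    ``Y`` is the indicator matrix scaled by its grand total; r and c its
    row/column masses. F and T are the left/right singular vectors of
    R^{-1/2}(Y - r c^T)C^{-1/2} and lambda_ca the squared singular values in
    descending order. ``row_scores`` = R^{-1/2} F Lambda^{1/2}.
    """

    Y: np.ndarray
    r: np.ndarray
    c: np.ndarray
    F: np.ndarray
    lambda_ca: np.ndarray
    T: np.ndarray
    row_scores: np.ndarray
    column_labels: list[str]
    diagnostic: str = ""

    @property
    def n_components(self) -> int:
        return len(self.lambda_ca)

    def total_inertia(self) -> float:
        return float(np.sum(self.lambda_ca))


@dataclass
class InstrumentMatrix:
    """Samples x IV factor scores with per-IV metadata.

    meta columns: iv_id, gene_id, component, eigenvalue, f_stat, n_snps,
    n_cis, n_hic, valid (bool; set by the validity screen), min_validity_q.
    """

    scores: pd.DataFrame
    meta: pd.DataFrame
    validity_tests: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.scores.columns) != self.meta["iv_id"].tolist():
            raise ValueError("scores columns must match meta iv_id order")

    @property
    def iv_ids(self) -> list[str]:
        return list(self.scores.columns)

    def for_gene(self, gene_id: str) -> list[str]:
        return self.meta.loc[self.meta["gene_id"] == gene_id, "iv_id"].tolist()

    def __len__(self) -> int:
        return self.scores.shape[1]

    def subset(self, samples: list[str]) -> "InstrumentMatrix":
        return InstrumentMatrix(self.scores.loc[samples], self.meta,
                                self.validity_tests)

    @staticmethod
    def empty(samples: list[str]) -> "InstrumentMatrix":
        meta = pd.DataFrame(
            columns=["iv_id", "gene_id", "component", "eigenvalue", "f_stat",
                     "n_snps", "n_cis", "n_hic"]
        )
        return InstrumentMatrix(pd.DataFrame(index=pd.Index(samples)), meta)


class CausalGraph:
    """DAG over gene nodes plus exogenous instrument nodes.

    Gene-gene edges carry ``effect`` and ``p``; iv->gene edges are fixed by
    instrument assignment. The gene subgraph is guaranteed acyclic; no edge
    ever enters an IV node.
    """

    def __init__(self) -> None:
        self.g = nx.DiGraph()
        self.metadata: dict = {}

    # -- construction -----------------------------------------------------
    def add_gene(self, gene_id: str) -> None:
        self.g.add_node(gene_id, kind=GENE_NODE)

    def add_iv(self, iv_id: str) -> None:
        self.g.add_node(iv_id, kind=IV_NODE)

    def add_edge(self, u: str, v: str, **attrs) -> None:
        if self.g.nodes[v]["kind"] == IV_NODE:
            raise ValueError("no edge may enter an IV node")
        etype = "iv->gene" if self.g.nodes[u]["kind"] == IV_NODE else "gene->gene"
        self.g.add_edge(u, v, etype=etype, **attrs)

    # -- views ------------------------------------------------------------
    @property
    def gene_nodes(self) -> list[str]:
        return sorted(n for n, d in self.g.nodes(data=True) if d["kind"] == GENE_NODE)

    @property
    def iv_nodes(self) -> list[str]:
        return sorted(n for n, d in self.g.nodes(data=True) if d["kind"] == IV_NODE)

    def gene_subgraph(self) -> nx.DiGraph:
        return self.g.subgraph(self.gene_nodes).copy()

    def gene_edges(self) -> list[tuple[str, str]]:
        return sorted(
            (u, v) for u, v, d in self.g.edges(data=True) if d["etype"] == "gene->gene"
        )

    def iv_edges(self) -> list[tuple[str, str]]:
        return sorted(
            (u, v) for u, v, d in self.g.edges(data=True) if d["etype"] == "iv->gene"
        )

    def gene_parents(self, gene_id: str) -> list[str]:
        return sorted(
            u for u in self.g.predecessors(gene_id)
            if self.g.nodes[u]["kind"] == GENE_NODE
        )

    def gene_children(self, gene_id: str) -> list[str]:
        return sorted(self.g.successors(gene_id))

    def ivs_of(self, gene_id: str) -> list[str]:
        return sorted(
            u for u in self.g.predecessors(gene_id)
            if self.g.nodes[u]["kind"] == IV_NODE
        )

    def has_iv(self, gene_id: str) -> bool:
        return len(self.ivs_of(gene_id)) > 0

    def assert_acyclic(self) -> None:
        if not nx.is_directed_acyclic_graph(self.gene_subgraph()):
            raise ValueError("gene subgraph contains a cycle")

    def topological_genes(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.gene_subgraph()))

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "edge_type": d["etype"],
             "effect": d.get("effect", np.nan), "p": d.get("p", np.nan)}
            for u, v, d in self.g.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["source", "target", "edge_type", "effect", "p"])
        return df.sort_values(["edge_type", "source", "target"]).reset_index(drop=True)

    def copy(self) -> "CausalGraph":
        new = CausalGraph()
        new.g = self.g.copy()
        new.metadata = dict(self.metadata)
        return new
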