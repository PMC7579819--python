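"""Readers and writers for the pipeline's plain-text formats.

Genotypes: minimal VCF (GT only) or TSV; expression/covariates: TSV with
samples in rows; Hi-C: 6-column BEDPE; gene annotation: BED-like TSV; truth
system: edge-list TSV plus a JSON manifest; networks: edge-list TSV and
GraphML; term sets: two-column TSV (term, gene).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    CausalGraph,
    ExpressionMatrix,
    GeneAnnotation,
    HiCContactMap,
    InstrumentMatrix,
    SnpPanel,
    TrueSystem,
)


# -- genotypes --------------------------------------------------------------

def write_genotypes_tsv(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index_label="sample")


def read_genotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_genotypes_vcf(genotypes: pd.DataFrame, panel: SnpPanel, path) -> None:
    """Minimal VCF 4.2 with GT only; REF/ALT are placeholder A/G."""
    samples = list(genotypes.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = panel.table["chrom"].unique()
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for _, row in panel.table.iterrows():
            calls = "\t".join(_GT[int(v)] for v in genotypes[row["snp_id"]])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t"
                     f"A\tG\t.\tPASS\t.\tGT\t{calls}\n")


def read_genotypes_vcf(path, samples: list[str] | None = None):
    """Parse a GT-only VCF into (genotype DataFrame, SnpPanel with maf from
    the sample allele frequencies)."""
    rows = []
    meta = []
    header_samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                header_samples = fields[9:]
                continue
            chrom, pos, snp_id = fields[0], int(fields[1]), fields[2]
            calls = [sum(int(a) for a in gt.replace("|", "/").split("/"))
                     for gt in fields[9:]]
            rows.append(calls)
            meta.append((snp_id, chrom, pos))
    geno = pd.DataFrame(
        np.array(rows).T, index=header_samples,
        columns=[m[0] for m in meta],
    )
    if samples is not None:
        geno = geno.loc[samples]
    freq = geno.to_numpy().mean(axis=0) / 2
    maf = np.clip(np.minimum(freq, 1 - freq), 1e-6, 0.5)
    panel = SnpPanel(pd.DataFrame(
        {"snp_id": [m[0] for m in meta], "chrom": [m[1] for m in meta],
         "pos": [m[2] for m in meta], "maf": maf}
    ))
    return geno, panel


# -- expression / covariates ------------------------------------------------

def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    out = expr.values.copy()
    out.insert(0, "cohort", expr.cohort)
    out.to_csv(path, sep="\t", index_label="sample")


def read_expression_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    cohort = df.pop("cohort")
    return ExpressionMatrix(df, cohort)


def write_covariates_tsv(covariates: pd.DataFrame, path) -> None:
    covariates.to_csv(path, sep="\t", index_label="sample")


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


# -- annotation / Hi-C ------------------------------------------------------

def write_genes_bed(genes: GeneAnnotation, path) -> None:
    genes.table[["chrom", "tss", "tes", "gene_id", "strand"]].to_csv(
        path, sep="\t", index=False, header=True
    )


def read_genes_bed(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t")
    return GeneAnnotation(df[["gene_id", "chrom", "tss", "tes", "strand"]])


def write_hic_bedpe(hic: HiCContactMap, path) -> None:
    hic.table.to_csv(path, sep="\t", index=False, header=False)


def read_hic_bedpe(path) -> HiCContactMap:
    df = pd.read_csv(path, sep="\t", header=None, names=HiCContactMap.COLUMNS)
    return HiCContactMap.from_records([tuple(r) for r in df.itertuples(index=False)])


def write_snp_panel_tsv(panel: SnpPanel, path) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


def read_snp_panel_tsv(path) -> SnpPanel:
    return SnpPanel(pd.read_csv(path, sep="\t"))


# -- truth ------------------------------------------------------------------

def write_true_system(system: TrueSystem, edges_path, manifest_path,
                      params: dict | None = None) -> None:
    rows = []
    for i, tgt in enumerate(system.gene_ids):
        for j, src in enumerate(system.gene_ids):
            if system.lambda_true[i, j] != 0:
                rows.append({"source": src, "target": tgt,
                             "effect": system.lambda_true[i, j]})
    pd.DataFrame(rows, columns=["source", "target", "effect"]).to_csv(
        edges_path, sep="\t", index=False
    )
    manifest = {
        "gene_ids": system.gene_ids,
        "sigma2": np.asarray(system.sigma2).tolist(),
        "genetic_effects": {k: [v[0], v[1]] for k, v in system.genetic_effects.items()},
        "deleted_edges_cases": sorted(list(e) for e in system.deleted_edges_cases),
        "params": params or {},
    }
    Path(manifest_path).write_text(json.dumps(manifest, indent=2))


# -- instruments / networks -------------------------------------------------

def write_instruments(ivs: InstrumentMatrix, scores_path, meta_path) -> None:
    ivs.scores.to_csv(scores_path, sep="\t", index_label="sample")
    ivs.meta.to_csv(meta_path, sep="\t", index=False)


def read_instruments(scores_path, meta_path) -> InstrumentMatrix:
    scores = pd.read_csv(scores_path, sep="\t", index_col="sample")
    meta = pd.read_csv(meta_path, sep="\t")
    return InstrumentMatrix(scores, meta)


def write_graph_tsv(graph: CausalGraph, path) -> None:
    graph.edge_table().to_csv(path, sep="\t", index=False)


def write_graph_graphml(graph: CausalGraph, path) -> None:
    nx.write_graphml(graph.g, path)


def read_graph_tsv(path, genes: list[str] | None = None) -> CausalGraph:
    """Edge-list TSV back to a CausalGraph. The TSV cannot carry isolated
    nodes; pass ``genes`` (e.g. the expression columns) to restore them."""
    df = pd.read_csv(path, sep="\t")
    graph = CausalGraph()
    gene_nodes = set(df.loc[df["edge_type"] == "gene->gene", "source"]) | set(
        df.loc[df["edge_type"] != "iv->gene", "target"]
    ) | set(df.loc[df["edge_type"] == "iv->gene", "target"])
    if genes is not None:
        gene_nodes |= set(genes)
    for g in sorted(gene_nodes):
        graph.add_gene(g)
    for iv in sorted(set(df.loc[df["edge_type"] == "iv->gene", "source"])):
        graph.add_iv(iv)
    for _, row in df.iterrows():
        graph.add_edge(row["source"], row["target"], effect=row.get("effect"),
                       p=row.get("p"))
    return graph


# -- term sets --------------------------------------------------------------

def write_term_sets(term_sets: dict[str, set[str]], path) -> None:
    rows = [{"term": t, "gene": g} for t in sorted(term_sets)
            for g in sorted(term_sets[t])]
    pd.DataFrame(rows, columns=["term", "gene"]).to_csv(path, sep="\t", index=False)


def read_term_sets(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for term, sub in df.groupby("term"):
        out[str(term)] = set(sub["gene"].astype(str))
    return out
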