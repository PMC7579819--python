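"""Replication and enrichment: test every learned gene-gene edge by simple
regression in an independent 25-sample expression set generated from the
same true system (the small-replication-cohort setting), and run
hypergeometric over-representation of the differential genes against
synthetic term sets.

Reads results/study/, results/network/, results/differential/;
writes results/replication/.
"""

import json
from pathlib import Path

import pandas as pd

from transnet import io as tio
from transnet.compare import replicate_edges
from transnet.datatypes import TrueSystem
from transnet.stats import hypergeom_enrichment
from transnet.synthetic import simulate_cohorts, simulate_genotypes, simulate_term_sets

STUDY = Path("results/study")
NET = Path("results/network")
DIFF = Path("results/differential")
OUT = Path("results/replication")
SEED = 601
N_REPLICATION = 25


def rebuild_system() -> TrueSystem:
    import numpy as np

    manifest = json.loads((STUDY / "truth_manifest.json").read_text())
    edges = pd.read_csv(STUDY / "truth_edges.tsv", sep="\t")
    gene_ids = manifest["gene_ids"]
    idx = {g: i for i, g in enumerate(gene_ids)}
    lam = np.zeros((len(gene_ids), len(gene_ids)))
    for _, row in edges.iterrows():
        lam[idx[row["target"]], idx[row["source"]]] = row["effect"]
    return TrueSystem(
        gene_ids=gene_ids, lambda_true=lam,
        genetic_effects={k: (v[0], v[1])
                         for k, v in manifest["genetic_effects"].items()},
        sigma2=np.array(manifest["sigma2"]),
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    graph = tio.read_graph_tsv(NET / "network_edges.tsv")
    panel = tio.read_snp_panel_tsv(STUDY / "snps.tsv")
    system = rebuild_system()
    geno = simulate_genotypes(panel, N_REPLICATION, seed=SEED,
                              sample_prefix="R")
    repl = simulate_cohorts(system, geno, n_cases=0,
                            n_controls=N_REPLICATION, seed=SEED + 1)
    table, fraction, excluded = replicate_edges(graph, repl)
    table.to_csv(OUT / "replication.tsv", sep="\t", index=False)
    print(f"replication at n={N_REPLICATION}: "
          f"{int(table['replicated'].sum())}/{len(table)} edges significant "
          f"after FDR (fraction {fraction:.2f}; {excluded} edges excluded)")

    genes = set(graph.gene_nodes)
    lost = pd.read_csv(DIFF / "lost_mediators.tsv", sep="\t")
    query = set(lost["mediator"]) | set(lost["downstream"])
    cand_path = DIFF / "candidates.tsv"
    if cand_path.exists():
        cand = pd.read_csv(cand_path, sep="\t")
        query |= set(cand.loc[cand["candidate"], "target"])
    if not query:
        print("no differential genes to enrich; skipping enrichment")
        return
    term_sets = simulate_term_sets(sorted(genes), n_terms=12, seed=SEED + 2)
    enr = hypergeom_enrichment(query & genes, term_sets, genes)
    enr.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    top = enr.iloc[0]
    print(f"enrichment of {sorted(query & genes)} over {len(term_sets)} "
          f"synthetic terms: top term {top['term']} "
          f"(k={top['k']}/M={top['M']}, p={top['p']:.3f}, q={top['q']:.3f})")


if __name__ == "__main__":
    main()
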