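"""Generate the synthetic study: genotypes under HWE, Hi-C contact anchors,
a known 30-gene causal system, and two cohorts differing by one deleted
mediator->downstream edge (G13 -> G14).

Writes the full dataset and the ground truth under results/study/.
"""

from pathlib import Path

from transnet import io as tio
from transnet.synthetic import simulate_study

SEED = 1
OUT = Path("results/study")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = simulate_study(seed=SEED)
    tio.write_genotypes_tsv(study.genotypes, OUT / "genotypes.tsv")
    tio.write_genotypes_vcf(study.genotypes, study.panel, OUT / "genotypes.vcf")
    tio.write_snp_panel_tsv(study.panel, OUT / "snps.tsv")
    tio.write_genes_bed(study.genes, OUT / "genes.bed")
    tio.write_hic_bedpe(study.hic, OUT / "hic.bedpe")
    tio.write_expression_tsv(study.expression, OUT / "expression_raw.tsv")
    tio.write_expression_tsv(study.residualized, OUT / "expression_residualized.tsv")
    tio.write_covariates_tsv(study.expression.covariates, OUT / "covariates.tsv")
    tio.write_true_system(study.system, OUT / "truth_edges.tsv",
                          OUT / "truth_manifest.json", params={"seed": SEED})
    n_ctrl = int((study.expression.cohort == "control").sum())
    n_case = int((study.expression.cohort == "case").sum())
    print(f"wrote study to {OUT}: {len(study.genes)} genes, "
          f"{len(study.panel)} SNPs, {len(study.hic)} Hi-C contacts, "
          f"{n_ctrl} controls + {n_case} cases")
    print(f"true gene-gene edges: {len(study.system.true_edges())}; "
          f"case-deleted edges: {sorted(study.system.deleted_edges_cases)}")


if __name__ == "__main__":
    main()
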