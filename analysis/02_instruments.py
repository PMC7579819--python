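"""Derive instrumental variables for every gene from the cis window and the
Hi-C-linked regions by correspondence analysis, screen them for strength
(F >= 10) and validity (no association with other transcripts given the
exposure), and report what survives.

Reads results/study/, writes results/instruments/.
"""

from pathlib import Path

from transnet import io as tio
from transnet.iv import build_instruments, validate_instruments

STUDY = Path("results/study")
OUT = Path("results/instruments")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = tio.read_expression_tsv(STUDY / "expression_residualized.tsv")
    geno = tio.read_genotypes_tsv(STUDY / "genotypes.tsv").loc[expr.samples]
    panel = tio.read_snp_panel_tsv(STUDY / "snps.tsv")
    genes = tio.read_genes_bed(STUDY / "genes.bed")
    hic = tio.read_hic_bedpe(STUDY / "hic.bedpe")

    candidates = build_instruments(geno, genes, panel, hic, expr)
    ivs = validate_instruments(candidates, expr, alpha_validity=0.05)
    tio.write_instruments(ivs, OUT / "instruments.tsv",
                          OUT / "instruments_meta.tsv")

    n_genes_with_iv = ivs.meta["gene_id"].nunique()
    print(f"candidate instruments after strength screen (F >= 10): "
          f"{len(candidates)}")
    print(f"instruments after validity screen: {len(ivs)} "
          f"across {n_genes_with_iv} genes "
          f"({len(ivs) / max(1, n_genes_with_iv):.2f} per instrumented gene)")
    if len(ivs):
        print(f"median strength F: {ivs.meta['f_stat'].median():.1f}; "
              f"regions pool {ivs.meta['n_snps'].median():.0f} SNPs "
              f"(cis + Hi-C) on median")


if __name__ == "__main__":
    main()
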