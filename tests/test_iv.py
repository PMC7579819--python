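"""Instrument engine: region selection geometry, correspondence analysis
against a dense eigendecomposition oracle, strength and validity screens."""

import numpy as np
import pandas as pd
import pytest

from transnet.datatypes import ExpressionMatrix, HiCContactMap, SnpPanel
from transnet.iv import (
    build_instruments,
    mca_factor_scores,
    select_region_snps,
    validate_instruments,
)
from transnet.synthetic import make_gene_annotation, simulate_genotypes


def ca_eigen_oracle(geno: pd.DataFrame) -> np.ndarray:
    """Independent oracle: eigenvalues of S^T S for the doubly standardized
    residual matrix, built with explicit loops and a dense eigensolver."""
    cols = []
    for snp in geno.columns:
        vals = geno[snp].to_numpy()
        for cat in sorted(np.unique(vals)):
            cols.append((vals == cat).astype(float))
    Z = np.column_stack(cols)
    Y = Z / Z.sum()
    r, c = Y.sum(axis=1), Y.sum(axis=0)
    S = np.empty_like(Y)
    for i in range(Y.shape[0]):
        for j in range(Y.shape[1]):
            S[i, j] = (Y[i, j] - r[i] * c[j]) / np.sqrt(r[i] * c[j])
    vals = np.linalg.eigvalsh(S.T @ S)[::-1]
    return vals[vals > 1e-12]


class TestRegionSelection:
    def test_inclusive_window_boundaries(self, small_panel, genes_single):
        # window start = tss - 40kb = 60000: pos 61000 in, pos 90000 in,
        # pos 300000 out
        region = select_region_snps(genes_single.table.iloc[0], small_panel,
                                    None, window=40_000)
        assert region.snp_ids == ["rs1", "rs2"]
        panel2 = SnpPanel(pd.DataFrame({
            "snp_id": ["rsA", "rsB"], "chrom": ["1", "1"],
            "pos": [59_999, 60_000], "maf": [0.3, 0.3],
        }))
        region2 = select_region_snps(genes_single.table.iloc[0], panel2,
                                     None, window=40_000)
        assert region2.snp_ids == ["rsB"]

    def test_empty_region_valid(self, genes_single):
        far = SnpPanel(pd.DataFrame({
            "snp_id": ["rs9"], "chrom": ["2"], "pos": [100], "maf": [0.2]
        }))
        region = select_region_snps(genes_single.table.iloc[0], far, None)
        assert len(region) == 0

    def test_hic_anchor_union_without_duplicates(self, genes_single):
        # distal anchor [500000, 510000) holds 3 SNPs; paired anchor overlaps
        # the gene window
        panel = SnpPanel(pd.DataFrame({
            "snp_id": [f"rs{i}" for i in range(5)],
            "chrom": ["1"] * 5,
            "pos": [100_500, 110_000, 500_001, 505_000, 509_999],
            "maf": [0.3] * 5,
        }))
        hic = HiCContactMap(pd.DataFrame(
            [["1", 99_999, 110_000, "1", 500_000, 510_000]],
            columns=HiCContactMap.COLUMNS,
        ))
        region = select_region_snps(genes_single.table.iloc[0], panel, hic)
        # brute-force: 2 cis + 3 inside the distal anchor
        assert len(region) == 5
        assert region.provenance["rs3"] == "hic"
        assert region.provenance["rs0"] == "cis"

    def test_order_independence_across_chrom_blocks(self, genes_single):
        # same SNPs, chromosome blocks listed in different order
        rows = [
            ("rsA", "1", 61_000, 0.3), ("rsB", "1", 90_000, 0.2),
            ("rsC", "2", 70_000, 0.4),
        ]
        panel1 = SnpPanel(pd.DataFrame(
            rows, columns=["snp_id", "chrom", "pos", "maf"]))
        panel2 = SnpPanel(pd.DataFrame(
            [rows[2], rows[0], rows[1]],
            columns=["snp_id", "chrom", "pos", "maf"]))
        r1 = select_region_snps(genes_single.table.iloc[0], panel1, None)
        r2 = select_region_snps(genes_single.table.iloc[0], panel2, None)
        assert r1.snp_ids == r2.snp_ids


class TestMCA:
    def test_monomorphic_gives_zero_components(self):
        geno = pd.DataFrame({"rs1": [1, 1, 1, 1]})
        d = mca_factor_scores(geno)
        assert d.n_components == 0
        assert "monomorphic" in d.diagnostic

    def test_mass_weighted_mean_of_scores_is_zero(self):
        rng = np.random.default_rng(4)
        geno = pd.DataFrame(rng.integers(0, 3, size=(40, 5)),
                            columns=[f"rs{i}" for i in range(5)])
        d = mca_factor_scores(geno)
        for k in range(d.n_components):
            assert abs(np.sum(d.r * d.row_scores[:, k])) < 1e-10

    def test_eigenvalues_match_dense_eigendecomposition(self):
        geno = pd.DataFrame({"rs1": [0, 1, 2, 1], "rs2": [2, 2, 0, 1]})
        d = mca_factor_scores(geno)
        oracle = ca_eigen_oracle(geno)
        assert np.allclose(d.lambda_ca, oracle[: d.n_components], atol=1e-8)

    def test_random_blocks_match_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            geno = pd.DataFrame(
                rng.integers(0, 3, size=(20, 6)),
                columns=[f"rs{i}" for i in range(6)],
            )
            d = mca_factor_scores(geno)
            oracle = ca_eigen_oracle(geno)
            assert np.allclose(d.lambda_ca, oracle[: d.n_components], atol=1e-8)

    def test_inertia_conservation_and_reconstruction(self):
        rng = np.random.default_rng(12)
        geno = pd.DataFrame(rng.integers(0, 3, size=(30, 4)),
                            columns=[f"rs{i}" for i in range(4)])
        d = mca_factor_scores(geno)
        S = (d.Y - np.outer(d.r, d.c)) / np.sqrt(np.outer(d.r, d.c))
        assert abs(d.total_inertia() - np.sum(S**2)) < 1e-8
        # R^1/2 F L^1/2 T^t C^1/2 + r c^t reproduces Y
        recon = (np.sqrt(d.r)[:, None] * d.F * np.sqrt(d.lambda_ca)[None, :]
                 ) @ d.T.T * np.sqrt(d.c)[None, :] + np.outer(d.r, d.c)
        assert np.allclose(recon, d.Y, atol=1e-8)

    def test_orthonormal_left_vectors(self):
        rng = np.random.default_rng(3)
        geno = pd.DataFrame(rng.integers(0, 3, size=(25, 3)),
                            columns=["a", "b", "c"])
        d = mca_factor_scores(geno)
        gram = d.F.T @ d.F
        assert np.allclose(gram, np.eye(d.n_components), atol=1e-10)


def _one_snp_study(seed, beta=0.5, n=300):
    """One gene, one causal cis SNP with effect beta."""
    genes = make_gene_annotation(n_genes=1)
    row = genes.table.iloc[0]
    panel = SnpPanel(pd.DataFrame({
        "snp_id": ["rs0"], "chrom": [row["chrom"]],
        "pos": [int(row["tss"]) + 500], "maf": [0.3],
    }))
    geno = simulate_genotypes(panel, n, seed=seed)
    rng = np.random.default_rng(seed + 1)
    y = beta * geno["rs0"].to_numpy() + rng.normal(size=n)
    expr = ExpressionMatrix(
        pd.DataFrame({"G00": y}, index=geno.index),
        pd.Series("control", index=geno.index),
    )
    return genes, panel, geno, expr


class TestBuildInstruments:
    def test_strong_single_snp_region_yields_instrument(self):
        # oracle: retention frequency over replicates
        kept = 0
        for seed in range(40):
            genes, panel, geno, expr = _one_snp_study(seed)
            ivs = build_instruments(geno, genes, panel, None, expr)
            if len(ivs) >= 1 and ivs.meta["f_stat"].max() > 10:
                kept += 1
        assert kept >= 38  # >= 0.95 retention

    def test_no_strength_yields_empty_matrix(self):
        genes, panel, geno, expr = _one_snp_study(0, beta=0.0)
        ivs = build_instruments(geno, genes, panel, None, expr,
                                f_threshold=1e6)
        assert len(ivs) == 0

    def test_retained_components_orthogonal_in_mass_metric(self, default_study):
        study = default_study
        ivs = build_instruments(study.genotypes, study.genes, study.panel,
                                study.hic, study.residualized)
        n = study.genotypes.shape[0]
        for gid, sub in ivs.meta.groupby("gene_id"):
            if len(sub) < 2:
                continue
            cols = ivs.scores[sub["iv_id"]].to_numpy()
            gram = (cols.T @ cols) / n  # uniform row masses
            off = gram - np.diag(np.diag(gram))
            assert np.max(np.abs(off)) < 1e-8

    def test_misaligned_samples_rejected(self):
        genes, panel, geno, expr = _one_snp_study(0)
        with pytest.raises(ValueError, match="aligned"):
            build_instruments(geno.iloc[::-1], genes, panel, None, expr)


class TestValidity:
    @staticmethod
    def _two_gene_frame(n, seed, pleiotropy=0.0):
        """Exposure e with one causal SNP; outcome o = 0.5 e (+ direct SNP
        effect when pleiotropy > 0)."""
        genes = make_gene_annotation(n_genes=1)
        row = genes.table.iloc[0]
        panel = SnpPanel(pd.DataFrame({
            "snp_id": ["rs0"], "chrom": [row["chrom"]],
            "pos": [int(row["tss"]) + 500], "maf": [0.3],
        }))
        geno = simulate_genotypes(panel, n, seed=seed)
        rng = np.random.default_rng(seed + 1)
        x = geno["rs0"].to_numpy()
        e = 0.5 * x + rng.normal(size=n)
        o = 0.5 * e + pleiotropy * x + rng.normal(size=n)
        expr = ExpressionMatrix(
            pd.DataFrame({"G00": e, "OUT": o}, index=geno.index),
            pd.Series("control", index=geno.index),
        )
        ivs = build_instruments(geno, genes, panel, None, expr)
        return ivs, expr

    def test_valid_iv_usually_retained(self):
        kept = tested = 0
        for seed in range(60):
            ivs, expr = self._two_gene_frame(500, seed)
            if len(ivs) == 0:
                continue
            tested += 1
            out = validate_instruments(ivs, expr, alpha_validity=0.05)
            kept += int(len(out) == len(ivs))
        assert tested >= 55
        assert kept / tested >= (1 - 0.05) - 0.03

    def test_pleiotropic_iv_removed(self):
        removed = tested = 0
        for seed in range(40):
            ivs, expr = self._two_gene_frame(500, seed, pleiotropy=0.4)
            if len(ivs) == 0:
                continue
            tested += 1
            out = validate_instruments(ivs, expr, alpha_validity=0.05)
            removed += int(len(out) < len(ivs))
        assert removed / tested >= 0.8

    def test_empty_matrix_passes_through(self, default_study):
        from transnet.datatypes import InstrumentMatrix

        empty = InstrumentMatrix.empty(default_study.residualized.samples)
        out = validate_instruments(empty, default_study.residualized)
        assert len(out) == 0
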