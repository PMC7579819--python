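"""Instrument generation: region SNP selection, multiple correspondence
analysis of genotype categories, strength screening, and validity screening.

The Mendelian-randomization logic: genotype categories {0,1,2} of the SNPs
in a gene's cis window (+/-40 kb around the gene span) and in Hi-C-linked
distal regions are expanded to an indicator table; correspondence analysis
of that table yields orthogonal factor scores that pool information across
SNPs into stronger genetic variables than any single SNP. A factor score is
kept as an instrumental variable for the gene when it is robustly associated
with the gene's transcript (regression F >= 10 by default), and it survives
the validity screen when it shows no association with any *other* transcript
conditional on its own (which would indicate pleiotropy or other exclusion-
restriction violations).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._ols import f_statistic, ols
from .datatypes import (
    CaDecomposition,
    ExpressionMatrix,
    GeneAnnotation,
    HiCContactMap,
    InstrumentMatrix,
    RegionSnpSet,
    SnpPanel,
)
from .stats import bh_adjust

__all__ = [
    "select_region_snps",
    "mca_factor_scores",
    "build_instruments",
    "validate_instruments",
]

DEFAULT_WINDOW = 40_000
DEFAULT_F_THRESHOLD = 10.0
MAX_COMPONENTS_PER_REGION = 5


def _snp_in_anchor(pos: np.ndarray, start: int, end: int) -> np.ndarray:
    # 1-based SNP position p occupies 0-based coordinate p-1
    return (pos - 1 >= start) & (pos - 1 < end)


def select_region_snps(
    gene: pd.Series,
    panel: SnpPanel,
    hic: HiCContactMap | None = None,
    window: int = DEFAULT_WINDOW,
) -> RegionSnpSet:
    """SNPs in the gene's cis window plus SNPs in Hi-C anchors whose paired
    anchor overlaps that window.

    The cis window ``[tss - window, tes + window]`` is inclusive on both
    ends; anchors are 0-based half-open. Provenance records 'cis' or 'hic'
    per SNP ('cis' wins when both apply). Order-independent: the result
    follows (chrom, pos) order regardless of panel row order.
    """
    lo = int(gene["tss"]) - window
    hi = int(gene["tes"]) + window
    tbl = panel.table
    pos = tbl["pos"].to_numpy()
    cis_mask = (tbl["chrom"] == gene["chrom"]).to_numpy() & (pos >= lo) & (pos <= hi)

    hic_mask = np.zeros(len(tbl), bool)
    if hic is not None and len(hic):
        h = hic.table
        # window [lo, hi] inclusive (1-based) == 0-based half-open [lo-1, hi)
        for a, b in ((("chrom_a", "start_a", "end_a"), ("chrom_b", "start_b", "end_b")),
                     (("chrom_b", "start_b", "end_b"), ("chrom_a", "start_a", "end_a"))):
            touching = h[
                (h[a[0]] == gene["chrom"])
                & (h[a[1]] < hi)
                & (h[a[2]] > max(0, lo - 1))
            ]
            for _, rec in touching.iterrows():
                on_chrom = (tbl["chrom"] == rec[b[0]]).to_numpy()
                hic_mask |= on_chrom & _snp_in_anchor(pos, int(rec[b[1]]), int(rec[b[2]]))

    cis_s = pd.Series(cis_mask, index=tbl.index)
    order = tbl[cis_mask | hic_mask].sort_values(["chrom", "pos"])
    snp_ids = order["snp_id"].tolist()
    prov = {
        sid: ("cis" if bool(cis_s.loc[idx]) else "hic")
        for sid, idx in zip(snp_ids, order.index)
    }
    return RegionSnpSet(gene_id=str(gene["gene_id"]), snp_ids=snp_ids, provenance=prov)


def mca_factor_scores(geno_sub: pd.DataFrame, tol: float = 1e-12) -> CaDecomposition:
    """Correspondence analysis of the genotype indicator table.

    Builds one 0/1 indicator column per *observed* genotype category of each
    SNP (zero-count categories dropped), scales the table by its grand total
    to obtain Y, forms row/column masses r and c, and takes the SVD of the
    doubly standardized residual R^{-1/2}(Y - r c^T)C^{-1/2} = F Lambda^{1/2} T^t.
    Row factor scores are R^{-1/2} F Lambda^{1/2}.

    Components with (relatively) zero singular value are dropped; a fully
    monomorphic block yields an empty decomposition with a diagnostic rather
    than raising.
    """
    if geno_sub.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if geno_sub.shape[1] < 1:
        raise ValueError("need at least 1 SNP")
    cols = []
    labels = []
    for snp in geno_sub.columns:
        vals = geno_sub[snp].to_numpy()
        for cat in sorted(np.unique(vals)):
            cols.append((vals == cat).astype(float))
            labels.append(f"{snp}={int(cat)}")
    Z = np.column_stack(cols)
    total = Z.sum()
    Y = Z / total
    r = Y.sum(axis=1)
    c = Y.sum(axis=0)
    S = (Y - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    keep = s > (tol + tol * s.max() if s.size else tol)
    # guard: strictly positive singular values well above floating noise
    keep = s > max(1e-9, 1e-9 * (s.max() if s.size else 1.0))
    U, s, Vt = U[:, keep], s[keep], Vt[keep, :]
    diagnostic = "" if s.size else "no informative components (monomorphic block)"
    row_scores = (U / np.sqrt(r)[:, None]) * s[None, :] if s.size else np.zeros((len(r), 0))
    return CaDecomposition(
        Y=Y, r=r, c=c, F=U, lambda_ca=s**2, T=Vt.T, row_scores=row_scores,
        column_labels=labels, diagnostic=diagnostic,
    )


def _retain_components(decomp: CaDecomposition, cap: int = MAX_COMPONENTS_PER_REGION) -> list[int]:
    """Kaiser-style retention: components with eigenvalue above the region's
    mean eigenvalue, capped at ``cap`` (eigenvalues are already descending).

    At least two components are always forwarded to the strength screen
    when available: for a single-SNP region the two CA axes split the
    additive and dominance contrasts, and the mean rule alone could discard
    the additive axis — the one a dosage effect loads on — before the
    F-statistic ever sees it."""
    lam = decomp.lambda_ca
    if lam.size == 0:
        return []
    keep = np.nonzero(lam > lam.mean())[0].tolist()
    floor = min(2, lam.size)
    if len(keep) < floor:
        keep = list(range(floor))
    return keep[:cap]


def build_instruments(
    genotypes: pd.DataFrame,
    genes: GeneAnnotation,
    panel: SnpPanel,
    hic: HiCContactMap | None,
    expr: ExpressionMatrix,
    window: int = DEFAULT_WINDOW,
    f_threshold: float = DEFAULT_F_THRESHOLD,
    max_components: int = MAX_COMPONENTS_PER_REGION,
) -> InstrumentMatrix:
    """Generate candidate instruments for every gene.

    Per gene: select region SNPs, run correspondence analysis, retain
    leading components (eigenvalue above the region mean, capped), then keep
    only components whose regression F against the gene's transcript clears
    ``f_threshold``. An empty result is valid — network learning then
    proceeds without instrument anchors.
    """
    if list(genotypes.index) != list(expr.values.index):
        raise ValueError("genotype and expression samples must be identical and aligned")
    score_cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for _, gene in genes.table.iterrows():
        gid = str(gene["gene_id"])
        if gid not in expr.values.columns:
            warnings.warn(f"gene {gid} absent from expression matrix; skipped")
            continue
        region = select_region_snps(gene, panel, hic, window=window)
        if len(region) == 0:
            continue
        decomp = mca_factor_scores(genotypes[region.snp_ids])
        retained = _retain_components(decomp, cap=max_components)
        y = expr.values[gid].to_numpy(float)
        n_cis = sum(1 for v in region.provenance.values() if v == "cis")
        for comp in retained:
            score = decomp.row_scores[:, comp]
            fstat = f_statistic(score, y)
            if fstat < f_threshold:
                continue
            iv_id = f"{gid}::ca{comp}"
            score_cols[iv_id] = score
            meta_rows.append(
                {"iv_id": iv_id, "gene_id": gid, "component": comp,
                 "eigenvalue": float(decomp.lambda_ca[comp]), "f_stat": fstat,
                 "n_snps": len(region), "n_cis": n_cis,
                 "n_hic": len(region) - n_cis}
            )
    if not meta_rows:
        return InstrumentMatrix.empty(list(expr.values.index))
    meta = pd.DataFrame(meta_rows)
    scores = pd.DataFrame(score_cols, index=expr.values.index)[meta["iv_id"].tolist()]
    return InstrumentMatrix(scores, meta)


def instruments_from_snps(
    genotypes: pd.DataFrame, snp_to_gene: dict[str, str]
) -> InstrumentMatrix:
    """Single-SNP instruments: centered genotype columns assigned to genes.

    Bypasses the correspondence-analysis pooling; used for controlled
    experiments where the instrument-to-gene map is known by construction.
    """
    cols: dict[str, np.ndarray] = {}
    rows = []
    for snp_id, gene_id in snp_to_gene.items():
        iv_id = f"{gene_id}::snp:{snp_id}"
        x = genotypes[snp_id].to_numpy(float)
        cols[iv_id] = x - x.mean()
        rows.append({"iv_id": iv_id, "gene_id": gene_id, "component": 0,
                     "eigenvalue": float("nan"), "f_stat": float("nan"),
                     "n_snps": 1, "n_cis": 1, "n_hic": 0})
    meta = pd.DataFrame(rows)
    scores = pd.DataFrame(cols, index=genotypes.index)[meta["iv_id"].tolist()]
    return InstrumentMatrix(scores, meta)


def validate_instruments(
    ivs: InstrumentMatrix,
    expr: ExpressionMatrix,
    alpha_validity: float = 0.05,
) -> InstrumentMatrix:
    """Exclusion-restriction screen.

    For each instrument of exposure gene e and every other gene o, test the
    instrument's association with o conditional on e (partial-regression
    t-test of o ~ iv + e). p-values are Benjamini-Hochberg adjusted across
    all instrument x outcome tests; an instrument with any adjusted p below
    ``alpha_validity`` is dropped. Surviving instruments keep their
    per-outcome p-values.
    """
    if len(ivs) == 0:
        return ivs
    genes = expr.values.columns
    rows = []
    for iv_id, gene_id in zip(ivs.meta["iv_id"], ivs.meta["gene_id"]):
        z = ivs.scores[iv_id].to_numpy(float)
        e = expr.values[gene_id].to_numpy(float)
        X = np.column_stack([z, e])
        for o in genes:
            if o == gene_id:
                continue
            y = expr.values[o].to_numpy(float)
            _, _, _, pvals, _, _ = ols(X, y)
            rows.append({"iv_id": iv_id, "outcome": o, "p": float(pvals[0])})
    tests = pd.DataFrame(rows)
    tests["q"] = bh_adjust(tests["p"].to_numpy())
    bad = set(tests.loc[tests["q"] < alpha_validity, "iv_id"])
    keep = [iv for iv in ivs.iv_ids if iv not in bad]
    meta = ivs.meta[ivs.meta["iv_id"].isin(keep)].reset_index(drop=True)
    minq = tests.groupby("iv_id")["q"].min()
    meta = meta.assign(min_validity_q=minq.reindex(meta["iv_id"]).to_numpy())
    return InstrumentMatrix(
        ivs.scores[keep], meta, validity_tests=tests.reset_index(drop=True)
    )
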