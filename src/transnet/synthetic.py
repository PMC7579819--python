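"""Synthetic genotype / Hi-C / two-cohort expression generator.

Emulates the data structure of a brain eQTL-style study: biallelic SNPs under
Hardy-Weinberg equilibrium, genes with cis windows, distal Hi-C contact
anchors carrying additional causal variants, a known recursive (acyclic)
linear effect system among genes, nuisance covariates, and two cohorts that
differ only by deletion of chosen mediator->downstream effects (the "loss of
mediator" mechanism). Expression noise is Gaussian: the downstream model
operates on normalized, covariate-residualized expression, which it treats as
multivariate normal.

Default scale — 30 genes in a chain-plus-hub topology, 5 SNPs per gene
(150 total), 2 distal anchors per gene, effect magnitudes in [0.5, 0.8],
cis genetic effects on every other gene, 300 samples per cohort, 3 continuous
plus 1 binary covariate — is small enough for desk-scale runs while keeping
instruments strong (single-SNP F-statistics well above 10 at n=300).

All randomness flows through a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneAnnotation,
    HiCContactMap,
    SnpPanel,
    TrueSystem,
)

__all__ = [
    "simulate_genotypes",
    "simulate_hic_map",
    "simulate_cohorts",
    "simulate_covariates",
    "residualize_expression",
    "make_chain_hub_system",
    "make_gene_annotation",
    "make_snp_panel",
    "simulate_term_sets",
    "SyntheticStudy",
    "simulate_study",
]


def simulate_genotypes(
    panel: SnpPanel, n_samples: int, seed: int, sample_prefix: str = "S"
) -> pd.DataFrame:
    """Draw additive genotype calls under HWE: each SNP ~ Binomial(2, maf).

    Returns a samples x SNPs DataFrame of values in {0, 1, 2}; deterministic
    given the seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    maf = panel.table["maf"].to_numpy(float)
    geno = rng.binomial(2, maf[None, :], size=(n_samples, len(maf)))
    samples = [f"{sample_prefix}{i:04d}" for i in range(n_samples)]
    return pd.DataFrame(geno, index=samples, columns=panel.snp_ids)


def _cis_window(row: pd.Series, window: int) -> tuple[int, int]:
    return int(row["tss"]) - window, int(row["tes"]) + window


def simulate_hic_map(
    genes: GeneAnnotation,
    n_distal_per_gene: int,
    anchor_width: int,
    min_gap: int,
    seed: int,
    window: int = 40_000,
    chrom_sizes: dict[str, int] | None = None,
) -> HiCContactMap:
    """Place, per gene, one anchor on the gene body and distal partner anchors.

    Distal anchors are sampled uniformly on the gene's chromosome at distance
    >= ``min_gap`` from the cis window ``[tss - window, tes + window]``; genes
    whose chromosome leaves no room are skipped with a warning. ``min_gap``
    must exceed the cis window width so a distal anchor can never double as
    the cis region.
    """
    widths = (genes.table["tes"] - genes.table["tss"] + 2 * window).to_numpy()
    if len(widths) and min_gap <= int(widths.max()):
        raise ValueError("min_gap must exceed the cis window width")
    rng = np.random.default_rng(seed)
    if chrom_sizes is None:
        chrom_sizes = {}
        for chrom, sub in genes.table.groupby("chrom"):
            chrom_sizes[chrom] = int(sub["tes"].max() + window + min_gap + 10 * anchor_width)
    records: list[tuple] = []
    for _, row in genes.table.iterrows():
        chrom = row["chrom"]
        lo, hi = _cis_window(row, window)
        # gene-body anchor (0-based half-open around the TSS)
        body_start = max(0, int(row["tss"]) - 1)
        body = (chrom, body_start, body_start + anchor_width)
        size = chrom_sizes[chrom]
        # candidate distal start positions keep the whole anchor >= min_gap away
        left_hi = lo - min_gap - anchor_width  # rightmost start on the left side
        right_lo = hi + min_gap  # leftmost start on the right side
        starts: list[int] = []
        for _ in range(n_distal_per_gene):
            side_right = bool(rng.integers(2))
            placed = None
            for right in (side_right, not side_right):
                if right and right_lo + anchor_width <= size:
                    placed = int(rng.integers(right_lo, size - anchor_width + 1))
                elif not right and left_hi >= 0:
                    placed = int(rng.integers(0, left_hi + 1))
                if placed is not None:
                    break
            if placed is None:
                warnings.warn(
                    f"no valid distal placement for gene {row['gene_id']}; skipped"
                )
                continue
            starts.append(placed)
        for s in starts:
            records.append((*body, chrom, s, s + anchor_width))
    if not records:
        return HiCContactMap(pd.DataFrame(columns=HiCContactMap.COLUMNS))
    return HiCContactMap.from_records(records)


def simulate_covariates(samples: list[str], seed: int, n_continuous: int = 3) -> pd.DataFrame:
    """Nuisance covariates: ``n_continuous`` standard-normal columns (RIN /
    age / PMI style) plus one binary column (sex / batch style)."""
    rng = np.random.default_rng(seed)
    n = len(samples)
    cols = {f"cov{i}": rng.normal(size=n) for i in range(1, n_continuous + 1)}
    cols["batch"] = rng.integers(0, 2, size=n).astype(float)
    return pd.DataFrame(cols, index=pd.Index(samples))


def simulate_cohorts(
    system: TrueSystem,
    genotypes: pd.DataFrame,
    n_cases: int,
    n_controls: int,
    seed: int,
    covariates: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Generate two-cohort expression from the recursive linear system.

    Controls use the full effect matrix; cases use it with the
    ``deleted_edges_cases`` entries zeroed. For each sample, exogenous noise
    U ~ N(0, diag(sigma2)) is drawn, genetic and covariate terms are added,
    and expression is solved gene by gene in the generating (topological)
    order: Z_i = sum_j lambda[i,j] Z_j + genetic_i + covariate_i + U_i.

    The first ``n_controls`` genotype rows become controls, the next
    ``n_cases`` become cases; both cohorts share the genotype-generating
    process.
    """
    p = len(system.gene_ids)
    n_total = n_cases + n_controls
    if genotypes.shape[0] < n_total:
        raise ValueError("genotype matrix has fewer samples than n_cases + n_controls")
    lam_control = system.lambda_true
    lam_case = system.lambda_cases()
    # acyclicity is structural (strictly lower triangular), but guard anyway
    if np.any(np.triu(lam_control) != 0):
        raise ValueError("effect matrix not triangularizable (cycle)")

    rng = np.random.default_rng(seed)
    samples = genotypes.index[:n_total].tolist()
    cohort = pd.Series(
        ["control"] * n_controls + ["case"] * n_cases, index=samples, name="cohort"
    )
    if covariates is None:
        n_cov = (
            system.covariate_loadings.shape[1]
            if system.covariate_loadings is not None
            else 4
        )
        covariates = simulate_covariates(
            samples, seed=int(rng.integers(2**31)), n_continuous=max(0, n_cov - 1)
        )
    covariates = covariates.loc[samples]

    sd = np.sqrt(np.asarray(system.sigma2, float))
    U = rng.normal(size=(n_total, p)) * sd[None, :]

    genetic = np.zeros((n_total, p))
    idx = system.index
    for snp_id, (gene_id, eff) in system.genetic_effects.items():
        genetic[:, idx[gene_id]] += eff * genotypes[snp_id].to_numpy(float)[:n_total]

    cov_term = np.zeros((n_total, p))
    if system.covariate_loadings is not None:
        cov_term = covariates.to_numpy(float) @ system.covariate_loadings.T

    base = U + genetic + cov_term
    Z = np.zeros((n_total, p))
    is_case = (cohort == "case").to_numpy()
    for i in range(p):  # generating order: strictly lower-triangular lambda
        upstream_control = Z[:, :i] @ lam_control[i, :i]
        upstream_case = Z[:, :i] @ lam_case[i, :i]
        Z[:, i] = base[:, i] + np.where(is_case, upstream_case, upstream_control)

    values = pd.DataFrame(Z, index=samples, columns=system.gene_ids)
    return ExpressionMatrix(values, cohort, covariates)


def residualize_expression(
    expr: ExpressionMatrix, covariates: pd.DataFrame | None = None
) -> ExpressionMatrix:
    """Replace each gene by its least-squares residual on covariates + intercept.

    Raises on rank-deficient covariate designs, naming the collinear columns.
    """
    if covariates is None:
        covariates = expr.covariates
    if covariates is None:
        raise ValueError("no covariates supplied")
    covariates = covariates.loc[expr.values.index]
    if covariates.isna().any().any():
        raise ValueError("covariates incomplete for some samples")
    X = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(covariates)
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {bad}")
    Y = expr.values.to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    values = pd.DataFrame(resid, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(values, expr.cohort.copy(), expr.covariates)


def _collinear_columns(covariates: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (greedy, for error messages)."""
    cols = list(covariates.columns)
    bad = []
    X = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(float)])
    for j, name in enumerate(cols):
        reduced = np.delete(X, j + 1, axis=1)
        if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(X):
            bad.append(name)
    return bad


# ---------------------------------------------------------------------------
# Default study construction
# ---------------------------------------------------------------------------

def make_gene_annotation(
    n_genes: int = 30,
    chrom: str = "1",
    start: int = 300_000,
    spacing: int = 600_000,
    gene_length: int = 20_000,
) -> GeneAnnotation:
    """Evenly spaced genes on one chromosome; spacing is wide enough that
    +/-40 kb cis windows never overlap."""
    rows = []
    for i in range(n_genes):
        tss = start + i * spacing
        rows.append(
            {"gene_id": f"G{i:02d}", "chrom": chrom, "tss": tss,
             "tes": tss + gene_length, "strand": "+" if i % 2 == 0 else "-"}
        )
    return GeneAnnotation(pd.DataFrame(rows))


def make_snp_panel(
    genes: GeneAnnotation,
    hic: HiCContactMap | None = None,
    n_cis_per_gene: int = 3,
    n_distal_per_gene: int = 2,
    window: int = 40_000,
    maf_range: tuple[float, float] = (0.2, 0.5),
    seed: int = 0,
) -> SnpPanel:
    """SNPs laid down inside each gene's cis window and, when a Hi-C map is
    given, inside the gene's distal anchors (so distal contacts genuinely
    carry variants)."""
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    hic_t = hic.table if hic is not None else None
    for _, row in genes.table.iterrows():
        lo, hi = _cis_window(row, window)
        cis_pos = np.linspace(max(1, lo + 1000), hi - 1000, n_cis_per_gene).astype(int)
        for pos in cis_pos:
            rows.append((f"rs{k:05d}", row["chrom"], int(pos),
                         float(rng.uniform(*maf_range))))
            k += 1
        if hic_t is not None and n_distal_per_gene > 0:
            body_lo = int(row["tss"]) - 1
            mine = hic_t[
                (hic_t["chrom_a"] == row["chrom"])
                & (hic_t["start_a"] <= body_lo)
                & (hic_t["end_a"] > body_lo)
            ]
            for _, rec in mine.head(n_distal_per_gene).iterrows():
                mid = int((rec["start_b"] + rec["end_b"]) // 2)
                rows.append((f"rs{k:05d}", rec["chrom_b"], mid + 1,
                             float(rng.uniform(*maf_range))))
                k += 1
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "maf"])
    df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    # nudge any coincident positions apart to keep strict ordering
    for chrom, sub in df.groupby("chrom"):
        pos = sub["pos"].to_numpy().copy()
        for i in range(1, len(pos)):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        df.loc[sub.index, "pos"] = pos
    return SnpPanel(df)


def _chain_hub_edges(n_genes: int) -> list[tuple[int, int]]:
    """Chain-plus-hub topology scaled to n_genes (designed at 30).

    G00 and G02 are hub broadcasters (out-degree >= 4, module cores); chains
    propagate effects to receptor sinks; G13 is a mediator with two upstream
    effectors and two downstream genes — its edge to G14 is the default
    case-deleted ("lost mediator") edge.
    """
    edges = [
        (0, 1), (0, 2), (0, 3), (0, 4), (0, 5),        # hub core G00
        (1, 6), (6, 7), (7, 8),                        # chain to receptor G08
        (2, 9), (2, 10), (2, 11), (2, 12),             # hub core G02
        (3, 13), (4, 13),                              # mediator G13, in-degree 2
        (13, 14), (13, 15),                            # its downstream genes
        (5, 16), (16, 17),                             # chain to receptor G17
        (9, 18), (10, 19), (11, 20),
    ]
    return [(u, v) for u, v in edges if u < n_genes and v < n_genes]


def make_chain_hub_system(
    n_genes: int = 30,
    panel: SnpPanel | None = None,
    genes: GeneAnnotation | None = None,
    effect_range: tuple[float, float] = (0.5, 0.8),
    genetic_effect: float = 0.5,
    distal_genetic_effect: float = 0.4,
    instrumented_fraction: float = 0.5,
    deleted_edges: set[tuple[str, str]] | frozenset = frozenset({("G13", "G14")}),
    covariate_sd: float = 0.3,
    n_covariates: int = 4,
    seed: int = 0,
    window: int = 40_000,
) -> TrueSystem:
    """Ground-truth system on the chain-plus-hub topology.

    Edge magnitudes are drawn uniformly from ``effect_range`` with
    alternating signs; every other gene (``instrumented_fraction`` of them)
    receives a cis genetic effect and, when its region holds a distal SNP, an
    additional distal genetic effect. Residual variances are 1.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:02d}" for i in range(n_genes)]
    lam = np.zeros((n_genes, n_genes))
    for k, (u, v) in enumerate(_chain_hub_edges(n_genes)):
        mag = rng.uniform(*effect_range)
        lam[v, u] = mag if k % 2 == 0 else -mag

    genetic_effects: dict[str, tuple[str, float]] = {}
    if panel is not None and genes is not None:
        used: set[str] = set()
        step = max(1, int(round(1 / instrumented_fraction)))
        for i in range(0, n_genes, step):
            row = genes.row(gene_ids[i])
            lo, hi = _cis_window(row, window)
            in_cis = panel.table[
                (panel.table["chrom"] == row["chrom"])
                & (panel.table["pos"] >= lo)
                & (panel.table["pos"] <= hi)
            ]
            if not in_cis.empty:
                genetic_effects[in_cis.iloc[0]["snp_id"]] = (gene_ids[i], genetic_effect)
            # one distal SNP: nearest unused SNP outside every cis window —
            # in the default layout that is a SNP inside this gene's own
            # Hi-C anchor, so the distal contact genuinely carries a causal
            # variant picked up by region selection
            if distal_genetic_effect != 0:
                cand = _nearest_free_distal(
                    panel, genes, window, gene_row=row, used=used
                )
                if cand is not None:
                    used.add(cand)
                    genetic_effects[cand] = (gene_ids[i], distal_genetic_effect)

    loadings = rng.normal(scale=covariate_sd, size=(n_genes, n_covariates))
    return TrueSystem(
        gene_ids=gene_ids,
        lambda_true=lam,
        genetic_effects=genetic_effects,
        sigma2=np.ones(n_genes),
        deleted_edges_cases=set(deleted_edges),
        covariate_loadings=loadings,
    )


def _nearest_free_distal(
    panel: SnpPanel,
    genes: GeneAnnotation,
    window: int,
    gene_row: pd.Series,
    used: set[str],
) -> str | None:
    """Unused SNP in no gene's cis window, closest to the gene's TSS."""
    tbl = panel.table
    same_chrom = tbl[tbl["chrom"] == gene_row["chrom"]]
    in_any_cis = np.zeros(len(same_chrom), bool)
    for _, g in genes.table.iterrows():
        if g["chrom"] != gene_row["chrom"]:
            continue
        lo, hi = _cis_window(g, window)
        in_any_cis |= (same_chrom["pos"] >= lo).to_numpy() & (
            same_chrom["pos"] <= hi
        ).to_numpy()
    free = same_chrom[~in_any_cis & ~same_chrom["snp_id"].isin(used)]
    if free.empty:
        return None
    dist = (free["pos"] - int(gene_row["tss"])).abs()
    return str(free.loc[dist.idxmin(), "snp_id"])


def simulate_term_sets(
    gene_ids: list[str], n_terms: int = 10, seed: int = 0, mean_size: int = 8
) -> dict[str, set[str]]:
    """Random gene-set annotation for enrichment smoke analyses."""
    rng = np.random.default_rng(seed)
    terms = {}
    for t in range(n_terms):
        size = max(2, int(rng.poisson(mean_size)))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        terms[f"TERM{t:02d}"] = set(members.tolist())
    return terms


def make_stability_study(
    n_per_class: int = 10,
    degrees: tuple[int, ...] = (1, 2, 3, 4, 5),
    n_samples: int = 1000,
    star_effect: float = 0.7,
    collider_effect: float = 0.45,
    n_filler_pairs: int = 200,
    filler_effect: float = 0.6,
    genetic_effect: float = 0.6,
    maf: float = 0.3,
    seed: int = 0,
):
    """Synthetic system sized for the permutation-stability experiment.

    The permutation design permutes sets of same-role, same-degree genes,
    so the network must hold, for every degree class d, at least
    ``n_per_class`` broadcasters of out-degree d and receptors of in-degree
    d, and be large enough that one permuted set owns only a small share of
    all edges.

    Topology: per degree d, ``n_per_class`` star blocks (one broadcaster
    feeding d leaf receptors) supply the out-degree-d broadcasters and the
    in-degree-1 receptors; for d >= 2, ``n_per_class`` collider blocks
    (d single-target broadcasters feeding one receptor) supply the
    in-degree-d receptors, with weaker in-effects so that conditioning on
    the common child keeps co-parent partial correlations below the
    skeleton threshold. ``n_filler_pairs`` independent instrumented pairs
    dilute the edge share of any one permuted set. Every broadcaster
    carries one cis SNP.

    Permuting a star broadcaster removes the common cause its children's
    partial correlations are conditioned on, so spurious sibling edges can
    surface among the orphaned leaves; permuting a terminal receptor has no
    downstream footprint. That asymmetry is the qualitative directionality
    support the permutation analysis looks for.

    Returns (TrueSystem, genotypes, SnpPanel, ExpressionMatrix).
    """
    gene_ids: list[str] = []
    edges: list[tuple[int, int]] = []
    effects: list[float] = []
    instrumented: list[int] = []

    def new_gene(tag: str) -> int:
        gene_ids.append(f"{tag}{len(gene_ids):03d}")
        return len(gene_ids) - 1

    for d in degrees:
        for _ in range(n_per_class):
            bc = new_gene("B")
            instrumented.append(bc)
            for _ in range(d):
                rec = new_gene("R")
                edges.append((bc, rec))
                effects.append(star_effect)
        if d >= 2:
            for _ in range(n_per_class):
                rec = new_gene("C")
                for _ in range(d):
                    src = new_gene("S")
                    instrumented.append(src)
                    edges.append((src, rec))
                    effects.append(collider_effect)
    for _ in range(n_filler_pairs):
        src = new_gene("F")
        tgt = new_gene("G")
        instrumented.append(src)
        edges.append((src, tgt))
        effects.append(filler_effect)

    p = len(gene_ids)
    lam = np.zeros((p, p))
    for k, (u, v) in enumerate(edges):
        lam[v, u] = effects[k] if k % 2 == 0 else -effects[k]
    # triangularity: collider-block sources are created after their
    # receptor; permute to a topological order
    order = _topological_order(p, edges)
    inv = np.argsort(order)
    lam = lam[np.ix_(order, order)]
    gene_ids_sorted = [gene_ids[i] for i in order]
    instrumented_sorted = [int(inv[i]) for i in instrumented]

    rows = [
        {"snp_id": f"rs{k:04d}", "chrom": "1", "pos": 1000 + 10_000 * k, "maf": maf}
        for k in range(len(instrumented_sorted))
    ]
    panel = SnpPanel(pd.DataFrame(rows))
    genetic_effects = {
        f"rs{k:04d}": (gene_ids_sorted[gi], genetic_effect)
        for k, gi in enumerate(instrumented_sorted)
    }
    system = TrueSystem(
        gene_ids=gene_ids_sorted, lambda_true=lam,
        genetic_effects=genetic_effects, sigma2=np.ones(p),
    )
    genotypes = simulate_genotypes(panel, n_samples, seed=seed)
    expression = simulate_cohorts(system, genotypes, n_cases=0,
                                  n_controls=n_samples, seed=seed + 1)
    return system, genotypes, panel, expression


def _topological_order(p: int, edges: list[tuple[int, int]]) -> np.ndarray:
    """Kahn order of node indices (deterministic, smallest index first)."""
    import heapq

    children: dict[int, list[int]] = {i: [] for i in range(p)}
    indeg = [0] * p
    for u, v in edges:
        children[u].append(v)
        indeg[v] += 1
    heap = [i for i in range(p) if indeg[i] == 0]
    heapq.heapify(heap)
    out = []
    while heap:
        u = heapq.heappop(heap)
        out.append(u)
        for v in children[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                heapq.heappush(heap, v)
    if len(out) != p:
        raise ValueError("cycle in edge list")
    return np.array(out)


def true_graph(system: TrueSystem) -> "CausalGraph":
    """CausalGraph holding the ground-truth gene-gene edges (no IV nodes);
    the oracle structure for parameter-recovery tests."""
    from .datatypes import CausalGraph

    g = CausalGraph()
    for gid in system.gene_ids:
        g.add_gene(gid)
    idx = system.index
    for src, tgt in sorted(system.true_edges()):
        g.add_edge(src, tgt, effect=float(system.lambda_true[idx[tgt], idx[src]]))
    g.metadata = {"source": "true_system"}
    return g


@dataclass
class SyntheticStudy:
    """Bundle of everything one synthetic study run produces."""

    panel: SnpPanel
    genes: GeneAnnotation
    hic: HiCContactMap
    genotypes: pd.DataFrame
    system: TrueSystem
    expression: ExpressionMatrix  # raw (covariate effects included)
    residualized: ExpressionMatrix

    @property
    def controls(self) -> ExpressionMatrix:
        return self.residualized.subset("control")

    @property
    def cases(self) -> ExpressionMatrix:
        return self.residualized.subset("case")


def simulate_study(
    seed: int,
    n_genes: int = 30,
    n_cases: int = 300,
    n_controls: int = 300,
    n_cis_per_gene: int = 3,
    n_distal_per_gene: int = 2,
    anchor_width: int = 10_000,
    min_gap: int = 150_000,
    window: int = 40_000,
    effect_range: tuple[float, float] = (0.5, 0.8),
    genetic_effect: float = 0.5,
    deleted_edges: set[tuple[str, str]] | frozenset = frozenset({("G13", "G14")}),
    covariate_sd: float = 0.3,
) -> SyntheticStudy:
    """Run the full generator with deterministic seed fan-out."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    genes = make_gene_annotation(n_genes=n_genes)
    hic = simulate_hic_map(
        genes, n_distal_per_gene=n_distal_per_gene, anchor_width=anchor_width,
        min_gap=min_gap, seed=seeds[0], window=window,
    )
    panel = make_snp_panel(
        genes, hic, n_cis_per_gene=n_cis_per_gene,
        n_distal_per_gene=n_distal_per_gene, window=window, seed=seeds[1],
    )
    system = make_chain_hub_system(
        n_genes=n_genes, panel=panel, genes=genes, effect_range=effect_range,
        genetic_effect=genetic_effect, deleted_edges=deleted_edges,
        covariate_sd=covariate_sd, seed=seeds[2], window=window,
    )
    genotypes = simulate_genotypes(panel, n_cases + n_controls, seed=seeds[3])
    expr = simulate_cohorts(
        system, genotypes, n_cases=n_cases, n_controls=n_controls, seed=seeds[4]
    )
    resid = residualize_expression(expr)
    return SyntheticStudy(panel, genes, hic, genotypes, system, expr, resid)
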