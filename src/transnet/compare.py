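"""Per-cohort structural-equation fits on a fixed network and the
case/control comparisons built on them.

The recursive Gaussian SEM is Z = Lambda Z + U with U ~ N(0, diag(sigma^2))
and Lambda lower triangular under a topological order of the learned DAG,
so node-wise least squares of each gene on its graph parents is the maximum-
likelihood estimator. The *exclusive effect* of a mediator on a downstream
gene is the mediator's coefficient after adjusting for the mediator's own
upstream genes; a mediator->downstream effect significant (95% CI excludes
zero) in controls but not in cases marks a *lost mediator*.

Core-based prediction uses ridge regression (loss 0.5||g - S b||^2 +
nu ||b||^2) with repeated five-fold cross-validation on unit-SD-scaled
expression; a core is a good predictor of a member when mean CV correlation
exceeds 0.6 and MSPE stays below 0.3 in both cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._ols import ci_from_fit, ols
from .datatypes import CausalGraph, ExpressionMatrix
from .properties import Module
from .stats import bh_adjust

__all__ = [
    "SEMFit",
    "fit_sem",
    "ExclusiveEffect",
    "exclusive_effect",
    "detect_lost_mediators",
    "core_prediction_cv",
    "evaluate_module_prediction",
    "conditional_novel_genes",
    "replicate_edges",
    "DEFAULT_NU_GRID",
]

DEFAULT_NU_GRID = tuple(10.0 ** e for e in range(-3, 3))  # 1e-3 .. 1e2


@dataclass
class SEMFit:
    cohort: str
    gene_ids: list[str]
    lambda_hat: np.ndarray  # [i, j] = effect of gene j on gene i
    delta_hat: np.ndarray  # per-gene residual variance
    edges: pd.DataFrame  # source, target, est, se, lo, hi
    ridge_fallback_edges: list[tuple[str, str]]


def fit_sem(
    expr_cohort: ExpressionMatrix,
    graph: CausalGraph,
    cond_cap: float = 1e8,
    level: float = 0.95,
) -> SEMFit:
    """Node-wise least-squares fit of the recursive SEM on the fixed DAG.

    Residual variances use n - k - 1 degrees of freedom. Parent designs
    whose condition number exceeds ``cond_cap`` fall back to a tiny ridge
    and are flagged, never silently."""
    graph.assert_acyclic()
    genes = list(expr_cohort.values.columns)
    col = {g: i for i, g in enumerate(genes)}
    X = expr_cohort.values.to_numpy(float)
    n, p = X.shape

    def parents_of(g: str) -> list[str]:
        # genes absent from the graph (e.g. isolated nodes dropped by an
        # edge-list round trip) are parentless
        return graph.gene_parents(g) if g in graph.g else []

    max_parents = max((len(parents_of(g)) for g in genes), default=0)
    if n < max_parents + 10:
        raise ValueError("cohort too small for the largest parent set")
    lam = np.zeros((p, p))
    delta = np.zeros(p)
    rows = []
    fallback = []
    for g in genes:
        parents = [q for q in parents_of(g) if q in col]
        y = X[:, col[g]]
        if not parents:
            delta[col[g]] = float(np.var(y, ddof=1))
            continue
        Xp = X[:, [col[q] for q in parents]]
        cond = np.linalg.cond(np.column_stack([np.ones(n), Xp]))
        if cond > cond_cap:
            XtX = Xp.T @ Xp + 1e-6 * np.eye(len(parents))
            beta = np.linalg.solve(XtX, Xp.T @ (y - y.mean()))
            resid = y - y.mean() - Xp @ beta
            df = n - len(parents) - 1
            sigma2 = float(resid @ resid) / df
            se = np.sqrt(np.diag(np.linalg.inv(XtX)) * sigma2)
            fallback.extend((q, g) for q in parents)
        else:
            beta, se, _, _, df, rss = ols(Xp, y)
            sigma2 = rss / df
        delta[col[g]] = sigma2
        for q, b_, s_ in zip(parents, beta, se):
            lam[col[g], col[q]] = b_
            lo, hi = ci_from_fit(float(b_), float(s_), df, level)
            rows.append({"source": q, "target": g, "est": float(b_),
                         "se": float(s_), "lo": lo, "hi": hi})
    edges = pd.DataFrame(rows, columns=["source", "target", "est", "se", "lo", "hi"])
    cohort = str(expr_cohort.cohort.iloc[0]) if len(expr_cohort.cohort) else ""
    return SEMFit(cohort, genes, lam, delta, edges, fallback)


@dataclass
class ExclusiveEffect:
    mediator: str
    downstream: str
    cohort: str
    estimate: float
    se: float
    lo: float
    hi: float

    @property
    def significant(self) -> bool:
        return not (self.lo <= 0.0 <= self.hi)


def exclusive_effect(
    expr_cohort: ExpressionMatrix,
    mediator: str,
    downstream: str,
    graph: CausalGraph,
    level: float = 0.95,
) -> ExclusiveEffect:
    """Effect of the mediator on a downstream gene adjusted for the
    mediator's upstream genes.

    Regresses downstream on {mediator} + parents(mediator); the mediator's
    coefficient with a t-based CI is the exclusive effect."""
    if (mediator, downstream) not in graph.gene_edges():
        raise ValueError(f"({mediator} -> {downstream}) is not a graph edge")
    parents = graph.gene_parents(mediator)
    if not parents:
        raise ValueError(f"mediator {mediator} has no upstream genes")
    V = expr_cohort.values
    design = [mediator] + parents
    Xd = V[design].to_numpy(float)
    if np.any(np.std(Xd, axis=0) == 0):
        raise ValueError("zero-variance regressor in exclusive-effect design")
    y = V[downstream].to_numpy(float)
    beta, se, _, _, df, _ = ols(Xd, y)
    lo, hi = ci_from_fit(float(beta[0]), float(se[0]), df, level)
    cohort = str(expr_cohort.cohort.iloc[0]) if len(expr_cohort.cohort) else ""
    return ExclusiveEffect(mediator, downstream, cohort,
                           float(beta[0]), float(se[0]), lo, hi)


def detect_lost_mediators(
    expr_cases: ExpressionMatrix,
    expr_controls: ExpressionMatrix,
    graph: CausalGraph,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Mediator->downstream pairs whose exclusive effect is significant in
    controls but not in cases.

    Candidate mediators have more than one upstream effector (in-degree >= 2)
    and at least one downstream gene. Returns the full two-cohort effect
    table (forest-plot ready) and the lost pairs."""
    from .properties import degrees_and_roles

    roles = degrees_and_roles(graph)
    candidates = roles.index[
        (roles["in_degree"] >= 2) & (roles["out_degree"] >= 1)
    ].tolist()
    rows = []
    lost = []
    for m in candidates:
        for d in graph.gene_children(m):
            if (m, d) not in graph.gene_edges():
                continue
            eff_ctrl = exclusive_effect(expr_controls, m, d, graph)
            eff_case = exclusive_effect(expr_cases, m, d, graph)
            is_lost = eff_ctrl.significant and not eff_case.significant
            for eff in (eff_ctrl, eff_case):
                rows.append(
                    {"mediator": m, "downstream": d, "cohort": eff.cohort,
                     "est": eff.estimate, "se": eff.se, "lo": eff.lo,
                     "hi": eff.hi, "significant": eff.significant,
                     "lost": is_lost}
                )
            if is_lost:
                lost.append((m, d))
    table = pd.DataFrame(
        rows, columns=["mediator", "downstream", "cohort", "est", "se",
                       "lo", "hi", "significant", "lost"]
    )
    return table, lost


# ---------------------------------------------------------------------------
# Core-based prediction
# ---------------------------------------------------------------------------

def _ridge_beta(X: np.ndarray, y: np.ndarray, nu: float) -> np.ndarray:
    """Minimizer of 0.5||y - X b||^2 + nu ||b||^2 (no intercept; inputs
    are centered/scaled upstream). nu = 0 reduces exactly to OLS."""
    q = X.shape[1]
    return np.linalg.solve(X.T @ X + 2.0 * nu * np.eye(q), X.T @ y)


def _lasso_beta(X: np.ndarray, y: np.ndarray, nu: float) -> np.ndarray:
    from sklearn.linear_model import Lasso, LinearRegression

    if nu == 0:
        return LinearRegression(fit_intercept=False).fit(X, y).coef_
    model = Lasso(alpha=nu / len(y), fit_intercept=False, max_iter=50_000)
    return model.fit(X, y).coef_


def _fold_ids(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    ids = np.arange(n) % k
    rng.shuffle(ids)
    return ids


def _pick_nu(X, y, nu_grid, k, rng, solver):
    ids = _fold_ids(len(y), k, rng)
    best_nu, best_err = nu_grid[0], np.inf
    for nu in nu_grid:
        sse = 0.0
        for f in range(k):
            tr, te = ids != f, ids == f
            beta = solver(X[tr], y[tr], nu)
            resid = y[te] - X[te] @ beta
            sse += float(resid @ resid)
        if sse < best_err - 1e-12:
            best_err, best_nu = sse, nu
    return best_nu


def core_prediction_cv(
    expr_cohort: ExpressionMatrix,
    module: Module,
    graph: CausalGraph,
    nu_grid=DEFAULT_NU_GRID,
    k: int = 5,
    repeats: int = 200,
    seed: int = 0,
    penalty: str = "ridge",
    predictors: str = "parents",
) -> pd.DataFrame:
    """Repeated k-fold CV prediction of each module member, one cohort.

    Predictor set S per member: its direct graph parents inside the module
    (which include the core whenever the core is a parent); a member with no
    in-module parent is predicted from the core alone. ``predictors='core'``
    forces the core-only variant for every member. All variables are scaled
    to unit SD once per cohort. Per repeat, fold assignments are drawn from
    the seed; nu is chosen on the training folds by inner k-fold CV; held-out
    predictions are pooled within the repeat to give one correlation and one
    MSPE, then averaged over repeats. Reruns with the same seed are
    bit-identical.

    Returns one row per member: target, predictors, n_predictors, corr,
    mspe, n_skipped_folds.
    """
    if len(module.members) < 2:
        raise ValueError("module must have at least one member besides the core")
    n = len(expr_cohort.values)
    if n < 5 * k:
        raise ValueError("cohort too small for k-fold CV")
    solver = _ridge_beta if penalty == "ridge" else _lasso_beta
    V = expr_cohort.values
    scaled = (V - V.mean()) / V.std(ddof=1)
    rng = np.random.default_rng(seed)
    rows = []
    for target in sorted(module.members - {module.core}):
        if predictors == "core":
            S = [module.core]
        else:
            S = [q for q in graph.gene_parents(target) if q in module.members]
            if not S:
                S = [module.core]
        X = scaled[S].to_numpy(float)
        y = scaled[target].to_numpy(float)
        corrs, mspes = [], []
        skipped = 0
        for _ in range(repeats):
            ids = _fold_ids(n, k, rng)
            pred = np.full(n, np.nan)
            for f in range(k):
                tr, te = ids != f, ids == f
                if np.std(y[tr]) == 0:
                    skipped += 1
                    continue
                nu = _pick_nu(X[tr], y[tr], nu_grid, k, rng, solver)
                beta = solver(X[tr], y[tr], nu)
                pred[te] = X[te] @ beta
            ok = ~np.isnan(pred)
            if ok.sum() < 3 or np.std(pred[ok]) == 0:
                continue
            corrs.append(float(np.corrcoef(pred[ok], y[ok])[0, 1]))
            mspes.append(float(np.mean((pred[ok] - y[ok]) ** 2)))
        rows.append(
            {"target": target, "predictors": ",".join(S), "n_predictors": len(S),
             "corr": float(np.mean(corrs)) if corrs else float("nan"),
             "mspe": float(np.mean(mspes)) if mspes else float("nan"),
             "n_skipped_folds": skipped}
        )
    return pd.DataFrame(rows)


def evaluate_module_prediction(
    expr_cases: ExpressionMatrix,
    expr_controls: ExpressionMatrix,
    module: Module,
    graph: CausalGraph,
    corr_threshold: float = 0.6,
    mspe_threshold: float = 0.3,
    **cv_kwargs,
) -> pd.DataFrame:
    """Two-cohort prediction table with the good-predictor call.

    good_predictor requires corr > ``corr_threshold`` and MSPE <
    ``mspe_threshold`` in BOTH cohorts."""
    res_ctrl = core_prediction_cv(expr_controls, module, graph, **cv_kwargs)
    res_case = core_prediction_cv(expr_cases, module, graph, **cv_kwargs)
    merged = res_ctrl.merge(
        res_case[["target", "corr", "mspe"]], on="target",
        suffixes=("_control", "_case"),
    )
    merged.insert(0, "core", module.core)
    merged["good_predictor"] = (
        (merged["corr_control"] > corr_threshold)
        & (merged["mspe_control"] < mspe_threshold)
        & (merged["corr_case"] > corr_threshold)
        & (merged["mspe_case"] < mspe_threshold)
    )
    return merged


def conditional_novel_genes(
    expr_cases: ExpressionMatrix,
    expr_controls: ExpressionMatrix,
    module: Module,
    known_genes: set[str],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Module members still associated with the core after conditioning on
    known disease genes, in both cohorts.

    For each member outside ``known_genes``: regress member ~ core +
    (known genes in the module); the core coefficient's p-value is BH-
    adjusted across tested members within each cohort; a candidate needs
    q < ``q_threshold`` in both. With no known gene in the module the test
    degrades to plain association and is flagged ``unconditional``.
    """
    known_in_module = sorted((known_genes & module.members) - {module.core})
    unconditional = len(known_in_module) == 0
    targets = sorted(
        g for g in module.members
        if g != module.core and g not in known_genes
    )
    out = {"target": targets}
    for label, expr in (("control", expr_controls), ("case", expr_cases)):
        pvals = []
        for g in targets:
            design_cols = [module.core] + [q for q in known_in_module if q != g]
            X = expr.values[design_cols].to_numpy(float)
            y = expr.values[g].to_numpy(float)
            _, _, _, p_, _, _ = ols(X, y)
            pvals.append(float(p_[0]))
        out[f"p_{label}"] = pvals
        out[f"q_{label}"] = bh_adjust(np.array(pvals)) if pvals else []
    df = pd.DataFrame(out)
    df["candidate"] = (df["q_control"] < q_threshold) & (df["q_case"] < q_threshold)
    df["unconditional"] = unconditional
    df.insert(0, "core", module.core)
    return df


def replicate_edges(
    graph: CausalGraph,
    replication_expr: pd.DataFrame | ExpressionMatrix,
    q_threshold: float = 0.05,
) -> tuple[pd.DataFrame, float, int]:
    """Replicate gene-gene edges in an independent expression set.

    Per edge, simple linear regression target ~ source gives a two-sided p;
    BH adjustment across tested edges; replicated means q < ``q_threshold``.
    Returns (edge table, replicated fraction, n excluded for missing genes).
    Small replication sets are allowed (t-based inference)."""
    V = replication_expr.values if isinstance(replication_expr, ExpressionMatrix) else replication_expr
    rows = []
    excluded = 0
    for u, v in graph.gene_edges():
        if u not in V.columns or v not in V.columns:
            excluded += 1
            continue
        x = V[u].to_numpy(float)
        y = V[v].to_numpy(float)
        beta, se, t, p_, df, _ = ols(x, y)
        rows.append({"source": u, "target": v, "est": float(beta[0]),
                     "p": float(p_[0])})
    if not rows:
        return (pd.DataFrame(columns=["source", "target", "est", "p", "q",
                                      "replicated"]), float("nan"), excluded)
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["replicated"] = table["q"] < q_threshold
    fraction = float(table["replicated"].mean())
    return table, fraction, excluded
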