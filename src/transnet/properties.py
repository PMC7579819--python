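"""Network properties: degrees, roles, pathways, cores, modules, and
degree-annotation association statistics.

Roles follow the standard broadcaster / receptor / mediator classification:
out-degree counts downstream genes directly affected by a gene, in-degree
counts upstream genes affecting it. Only gene->gene edges count toward
degrees; instrument edges set the ``has_iv`` flag. A gene's effect
propagates downstream along a pathway until it reaches a receptor; genes
with many out-edges are "cores" and the subnetwork a core influences, with
receptor genes as its boundary, is its module.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import CausalGraph

__all__ = [
    "degrees_and_roles",
    "downstream_pathways",
    "find_modules",
    "Module",
    "OrResult",
    "annotation_degree_odds_ratio",
    "annotation_degree_proportions",
]


def degrees_and_roles(graph: CausalGraph) -> pd.DataFrame:
    """Per-gene in/out/total degree, role, and instrument flag.

    Roles partition the genes: broadcaster (out>0, in=0), receptor (in>0,
    out=0), mediator (both), isolated (neither).
    """
    sub = graph.gene_subgraph()
    rows = []
    for g in graph.gene_nodes:
        indeg = sub.in_degree(g)
        outdeg = sub.out_degree(g)
        if outdeg > 0 and indeg == 0:
            role = "broadcaster"
        elif indeg > 0 and outdeg == 0:
            role = "receptor"
        elif indeg > 0 and outdeg > 0:
            role = "mediator"
        else:
            role = "isolated"
        rows.append(
            {"gene_id": g, "in_degree": indeg, "out_degree": outdeg,
             "degree": indeg + outdeg, "role": role,
             "has_iv": graph.has_iv(g)}
        )
    return pd.DataFrame(rows).set_index("gene_id")


def downstream_pathways(
    graph: CausalGraph, gene: str, max_paths: int = 10_000
) -> tuple[list[list[str]], bool]:
    """All simple directed paths from ``gene`` to any receptor.

    Returns (paths, overflow); overflow is True when enumeration was cut at
    ``max_paths``. A receptor input yields an empty list.
    """
    sub = graph.gene_subgraph()
    if gene not in sub:
        raise KeyError(gene)
    roles = degrees_and_roles(graph)
    receptors = set(roles.index[roles["role"] == "receptor"])
    paths: list[list[str]] = []
    overflow = False
    stack = [(gene, [gene])]
    while stack:
        node, path = stack.pop()
        for child in sorted(sub.successors(node), reverse=True):
            new = path + [child]
            if child in receptors:
                paths.append(new)
                if len(paths) >= max_paths:
                    overflow = True
                    stack.clear()
                    break
            else:
                stack.append((child, new))
    return paths, overflow


@dataclass
class Module:
    """A core gene and the subnetwork it influences."""

    core: str
    members: set[str]  # includes the core
    boundary_receptors: set[str]
    max_path_length: int

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


def find_modules(graph: CausalGraph, core_min_outdegree: int = 4) -> list[Module]:
    """Modules around every core (gene with out-degree >= threshold).

    A module is the core plus its descendant closure; receptors bound the
    closure naturally (they have no out-edges), so boundary receptors are
    exactly the zero-out-degree members. Overlapping modules are allowed.
    """
    sub = graph.gene_subgraph()
    modules = []
    for core in graph.gene_nodes:
        if sub.out_degree(core) < core_min_outdegree:
            continue
        members = {core} | nx.descendants(sub, core)
        msub = sub.subgraph(members)
        boundary = {g for g in members if msub.out_degree(g) == 0 and g != core}
        # longest simple path from core in a DAG via topological relaxation
        topo = list(nx.topological_sort(msub))
        longest = {g: (0 if g == core else -np.inf) for g in members}
        for u in topo:
            if longest[u] == -np.inf:
                continue
            for v in msub.successors(u):
                longest[v] = max(longest[v], longest[u] + 1)
        max_len = int(max(v for v in longest.values() if v != -np.inf))
        modules.append(Module(core=core, members=members,
                              boundary_receptors=boundary, max_path_length=max_len))
    return modules


@dataclass
class OrResult:
    """2x2 odds ratio with Woolf 95% CI."""

    a: int  # high-degree & flagged
    b: int  # high-degree & unflagged
    c: int  # low-degree & flagged
    d: int  # low-degree & unflagged
    odds_ratio: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool
    note: str = ""


def annotation_degree_odds_ratio(
    roles: pd.DataFrame,
    flag: pd.Series,
    degree_threshold: int = 3,
    degree_kind: str = "total",
) -> OrResult:
    """Odds ratio relating high connectivity to a per-gene boolean annotation.

    Cross-tabulates degree >= threshold (``degree_kind``: 'total' or 'out')
    against the flag; OR = ad/bc with the Haldane-Anscombe +0.5 correction
    when any cell is zero, and a Woolf log-scale 95% CI.
    """
    col = "degree" if degree_kind == "total" else "out_degree"
    flag = flag.reindex(roles.index)
    if flag.isna().any():
        raise ValueError("flag must be defined for all genes")
    flag = flag.astype(bool)
    high = roles[col] >= degree_threshold
    a = int((high & flag).sum())
    b = int((high & ~flag).sum())
    c = int((~high & flag).sum())
    d = int((~high & ~flag).sum())
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return OrResult(a, b, c, d, float("nan"), float("nan"), float("nan"),
                        False, note="degenerate margin; OR undefined")
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    )
    orr = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo = float(np.exp(np.log(orr) - 1.96 * se))
    hi = float(np.exp(np.log(orr) + 1.96 * se))
    return OrResult(a, b, c, d, float(orr), lo, hi, corrected)


def annotation_degree_proportions(
    roles: pd.DataFrame,
    flag: pd.Series,
    degree_threshold: int = 4,
    degree_kind: str = "total",
) -> dict[str, float]:
    """Proportion of high-degree genes among flagged and unflagged genes.

    Returns {"flagged": ..., "unflagged": ...}; an empty class yields NaN
    for that entry (flagged in the value, not raised).
    """
    col = "degree" if degree_kind == "total" else "out_degree"
    flag = flag.reindex(roles.index)
    if flag.isna().any():
        raise ValueError("flag must be defined for all genes")
    flag = flag.astype(bool)
    high = roles[col] >= degree_threshold
    out = {}
    for label, mask in (("flagged", flag), ("unflagged", ~flag)):
        out[label] = float(high[mask].mean()) if mask.any() else float("nan")
    return out
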