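"""Differential regulation between cohorts on the fixed network: per-cohort
SEM fits, exclusive effects of mediators on their downstream genes, lost
mediators (significant in controls, not in cases), core-based prediction
with repeated cross-validation, and conditional candidate calling.

Reads results/study/ and results/network/, writes results/differential/.
"""

from pathlib import Path

import pandas as pd

from transnet import io as tio
from transnet.compare import (
    conditional_novel_genes,
    detect_lost_mediators,
    evaluate_module_prediction,
    fit_sem,
)
from transnet.properties import find_modules

STUDY = Path("results/study")
NET = Path("results/network")
OUT = Path("results/differential")
KNOWN_GENES = {"G01", "G03", "G09"}  # plays the known disease-gene list
SEED = 501


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = tio.read_expression_tsv(STUDY / "expression_residualized.tsv")
    graph = tio.read_graph_tsv(NET / "network_edges.tsv",
                               genes=expr.gene_ids)
    cases, controls = expr.subset("case"), expr.subset("control")

    for label, cohort in (("controls", controls), ("cases", cases)):
        fit = fit_sem(cohort, graph)
        fit.edges.to_csv(OUT / f"sem_{label}.tsv", sep="\t", index=False)

    table, lost = detect_lost_mediators(cases, controls, graph)
    table.to_csv(OUT / "exclusive_effects.tsv", sep="\t", index=False)
    pd.DataFrame(lost, columns=["mediator", "downstream"]).to_csv(
        OUT / "lost_mediators.tsv", sep="\t", index=False)
    n_candidates = table["mediator"].nunique()
    print(f"candidate mediators (in-degree >= 2, out-degree >= 1): "
          f"{n_candidates}")
    print(f"lost mediator pairs (control-significant, case-non-significant): "
          f"{lost}")
    for _, row in table[table["lost"]].iterrows():
        print(f"  {row['mediator']} -> {row['downstream']} [{row['cohort']}]: "
              f"{row['est']:+.3f} [{row['lo']:+.3f}, {row['hi']:+.3f}]")

    frames, cand_frames = [], []
    for module in find_modules(graph, core_min_outdegree=4):
        pred = evaluate_module_prediction(cases, controls, module, graph,
                                          repeats=50, seed=SEED)
        frames.append(pred)
        good = pred[pred["good_predictor"]]
        print(f"module {module.core}: {len(good)}/{len(pred)} members "
              f"well predicted (corr > 0.6, MSPE < 0.3 in both cohorts)")
        if len(good):
            cand = conditional_novel_genes(cases, controls, module,
                                           KNOWN_GENES)
            cand_frames.append(cand)
            hits = cand[cand["candidate"]]["target"].tolist()
            print(f"  conditional candidates beyond known genes: {hits}")
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            OUT / "prediction.tsv", sep="\t", index=False)
    if cand_frames:
        pd.concat(cand_frames, ignore_index=True).to_csv(
            OUT / "candidates.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
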