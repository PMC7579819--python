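# Methods

This note records the models, the concrete algorithmic choices made where
the design was genuinely open, the synthetic-data conditions, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and generator

Expression is a recursive linear Gaussian SEM over p genes,
Z = ΛZ + ΓX + BC + U, with Λ strictly lower triangular under the generating
order (hence acyclic), X additive genotype dosages in {0,1,2} drawn per SNP
as Binomial(2, maf) under Hardy–Weinberg equilibrium, C nuisance covariates
(three standard-normal columns plus one binary, loadings N(0, 0.3²) by
default), and U independent Gaussian noise with unit variances. The model
operates on normalized, covariate-residualized expression, which is why no
count-level RNA-seq simulation is attempted; multivariate normality is the
model's own assumption.

The default study emulates the structure of a brain eQTL cohort at desk
scale, and these defaults are the study conditions for every test:

* 30 genes in a chain-plus-hub topology (two hub cores of out-degree ≥ 4,
  chains ending in receptors, one mediator with two upstream effectors),
  21 edges with |β| drawn uniformly from [0.5, 0.8], alternating sign;
* 150 SNPs: 3 per cis window plus 2 at the midpoints of the gene's distal
  Hi-C anchors (anchors ≥ 150 kb from any cis window, 10 kb wide);
* cis genetic effects of 0.5 and distal effects of 0.4 on every other gene
  ("IVs on half the genes"), maf ~ U(0.2, 0.5) — single-SNP F-statistics
  are comfortably above the weak-instrument bar at n = 300;
* 300 samples per cohort; cases differ from controls only by deletion of
  the mediator edge G13→G14 ("loss of mediator"); effect-size shrinkage is
  available as an option but is not the default mechanism;
* all randomness flows from one integer seed through
  `numpy.random.SeedSequence` fan-out; reruns are bit-identical.

Coordinate conventions: SNP positions are 1-based (VCF), Hi-C anchors and
BED intervals 0-based half-open, cis windows [tss − w, tes + w] inclusive
with w = 40 kb, strand ignored for windowing.

What the generator does *not* emulate: linkage disequilibrium, population
structure, count noise / library-size effects, cell-type composition,
nonlinear regulation, and feedback. Passing tests therefore demonstrate
correctness of the machinery and calibration under the stated model, not
performance on real cohort data.

## Instrument generation

Per gene, the region is the union of cis-window SNPs and SNPs inside Hi-C
anchors whose partner anchor overlaps the window. The genotype categories
observed in the region are expanded to a 0/1 indicator table, scaled by its
grand total (Y), and decomposed by correspondence analysis:
SVD of R^(−1/2)(Y − rcᵀ)C^(−1/2), row factor scores R^(−1/2)FΛ^(1/2).
Numerically, singular values below 10⁻⁹ (relative) are treated as zero; a
fully monomorphic region yields an empty decomposition with a diagnostic
rather than an error.

Component retention forwards the components whose eigenvalue exceeds the
region mean (Kaiser-style), capped at 5 — but always at least two when two
exist: for a single-SNP region the two CA axes separate the additive and
dominance contrasts, and the dominance axis often carries more inertia, so
the mean rule alone could discard the additive axis (the one a dosage
effect loads on) before the strength screen ever sees it.

The strength screen keeps components with regression F ≥ 10 against the
gene's transcript (the standard weak-instrument convention; configurable).
The validity screen tests each instrument against every other transcript
conditional on its own (partial-regression t-test), Benjamini–Hochberg
across all instrument × outcome tests, and drops instruments with any
adjusted p < 0.05. This guards the exclusion restriction against, e.g., a
distal anchor that happens to overlap another gene's cis region; it is a
screen, not a guarantee — modest pleiotropy can survive at these sample
sizes.

## Network learning

A deterministic three-stage algorithm (recorded in the graph metadata):

1. **Skeleton.** Each gene is regressed on all other genes; the pair {i, j}
   is kept when either direction's coefficient p-value is below the tuning
   level α. α is the per-coefficient threshold: this reads the tuning grid
   {0.01, 0.005, 0.001, 0.0005} directly as significance levels and matches
   the null expectation of ~α per tested direction. A per-neighborhood
   Bonferroni option (`multiplicity="bonferroni"`) is provided and is the
   right choice for panels of hundreds of genes or more, where the raw rule
   would admit ~α·p(p−1) false edges; the permutation-stability experiment
   (hundreds of genes) uses it. The p-values come from the precision matrix
   of the centered data — identical to the per-gene OLS t-tests but one
   p × p inversion instead of p regressions — with a per-gene OLS fallback
   when n ≤ p. The skeleton is monotone in α by construction.

2. **Instrument orientation.** For an edge {A, B}: the association of A's
   instruments, jointly (F-test), with B is evidence for A→B — the
   instruments are exogenous and can reach B only through A. Joint testing
   matters: a single component at F ≈ 10 has little power against the
   attenuated downstream signal. Thresholds: p < 0.01 orients positively;
   when only one endpoint is instrumented and its test is clearly null
   (p > 0.5), the edge is oriented *toward* the instrumented gene (an
   instrumented upstream gene must leak into its target); the ambiguous
   band defers to stage 3. Cyclic residues among instrument-oriented edges
   are resolved by removing the weakest-evidence edge per cycle (counted in
   metadata).

3. **Score completion.** Remaining edges are oriented by an equal-variance
   Gaussian score — total residual sum of squares across nodes — first in a
   deterministic greedy pass (larger RSS reduction wins, acyclicity
   enforced), then by reversal hill-climbing until no single reversal
   improves the total (capped at 50 sweeps). The equal-variance assumption
   is what makes Markov-equivalent orientations (e.g. the leaves of a hub)
   identifiable at all; with free per-node variances they are exactly
   score-tied. It is reasonable for normalized, residualized expression and
   is stated here as a modeling choice. Edge effects and p-values are
   refit by OLS on the final parent sets.

Tuning minimizes the mean pairwise normalized Hamming distance (directed
edge-status disagreements over ordered gene pairs; a reversal counts 2)
across networks learned on shared random subsamples (default 75% of
samples, without replacement), ties toward the sparser level. Instrument
edges are fixed by assignment and excluded from the distance.

The pipeline learns structure on the **control cohort** by default
(`structure_cohort` = control; case/pooled available). Pooling halves the
partial signal of any case-deleted edge, which is exactly the signal the
differential stage needs; the control network is the natural reference for
"what cases lost".

Permutation stability permutes the expression vectors (independently) of
up to 10 sampled same-role, same-degree genes, relearns at the stored
settings, and reports 1 − changed/original edge statuses, clamped to
[0, 1]. Degree 0 selects isolated genes (used in tests). The qualitative
broadcaster-vs-receptor comparison uses changed counts per permuted gene,
paired across degree classes, because eligibility counts per class can
differ.

The dedicated stability study (`make_stability_study`) is sized so that a
10-gene permuted set owns a small share of all edges: per degree d, 10
star blocks (broadcaster → d leaf receptors, β = 0.7) and, for d ≥ 2, 10
collider blocks (d single-target broadcasters → one receptor, β = 0.45 so
that conditioning on the common child keeps co-parent partial correlations
below threshold), plus 200 independent pairs (β = 0.6); 780 genes, 440
edges, n = 1000. Permuting a star broadcaster removes the common cause its
children's partial correlations are conditioned on, so spurious sibling
edges can surface; permuting a terminal receptor has no downstream
footprint — that asymmetry is the directionality support the permutation
design probes.

## Cohort comparison

On the fixed DAG, node-wise OLS of each gene on its graph parents is the
MLE of the recursive Gaussian SEM; residual variances use n − k − 1 degrees
of freedom and CIs use t-quantiles throughout. Parent designs with
condition number above 10⁸ fall back to a tiny ridge and are flagged. The
exclusive effect of mediator m on downstream d is m's coefficient in the
regression of d on {m} ∪ parents(m) — adjusting for the mediator's
upstream genes per the definition; adjusting additionally for d's other
parents is exposed as a flag but is not the default. Candidate mediators
have in-degree ≥ 2 and out-degree ≥ 1; a pair is *lost* when the exclusive
effect is significant (95% CI excludes 0) in controls and non-significant
in cases. A formal interaction test would be stricter; the CI-overlap rule
matches forest-plot reporting and is the default.

Core-based prediction scales each cohort's expression to unit SD once,
takes as predictors the member's graph parents inside the module (falling
back to the core for parentless members; a core-only variant is available),
and runs repeated 5-fold CV (200 repeats by default) of ridge regression —
loss ½‖g − Sβ‖² + ν‖β‖², ν chosen on the training folds by inner 5-fold CV
over the grid 10⁻³…10² (the printed squared-L1 penalty is interpreted as
the squared-L2 the surrounding text describes; a lasso switch exists).
ν = 0 reduces exactly to OLS. A member is well predicted when mean CV
correlation > 0.6 and MSPE < 0.3 in both cohorts. Note the implied bar: on
the unit-SD scale MSPE ≈ 1 − R², so the rule demands R² ≳ 0.7 — a member at
exactly 70% explained variance sits on the threshold and is classified
"good" only about a fifth of the time; with the default edge range
[0.5, 0.8] and unit noise no synthetic member reaches it, and the
conditional-candidate stage of the default pipeline is gated off
accordingly.

Conditional candidate calling regresses each non-known member on the core
plus the known genes in the module, BH-adjusts the core-coefficient
p-values across members within each cohort, and requires q < 0.05 in both;
an empty conditioning set degrades to plain association and is flagged.
Edge replication fits target ~ source per edge in the independent set
(t-based inference, small n allowed; the emulated replication cohort has
25 samples), BH across edges, replicated ⟺ q < 0.05.

Enrichment computes the exact hypergeometric upper tail by summing the
tail directly in log space (gammaln binomials) — identical to
1 − CDF(k − 1) but without the cancellation — and BH-adjusts across terms.
The background defaults to the genes of the analyzed network and is
overridable.

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses: 20 study replicates at n = 500 for structure
recovery; 30 noise replicates for null calibration; 100 replicates at
n = 1000 for SEM recovery; 100 + 50 replicates at n = 200/cohort for
lost-mediator power and false flags; 3 datasets × 100 CV repeats for
prediction calibration; one stability study with 4 permutations per
role × degree. These sizes keep a full run to a few minutes on one CPU
while holding Monte-Carlo error well inside the reported precision.

## Known limitations

* The validity screen is underpowered against weak pleiotropy at n ≈ 300;
  contaminated instruments can mis-orient an occasional edge (the score
  completion usually, not always, corrects it).
* Full-conditioning neighborhood selection can admit collider-induced
  co-parent edges when both in-effects are strong; these appear as a small
  precision loss around multi-parent nodes.
* The equal-variance completion is a tie-breaking assumption; on data with
  grossly heteroscedastic residuals unanchored edges orient less reliably.
* Cross-region instrument decorrelation is not enforced: instruments of
  different genes may correlate (e.g. through shared Hi-C anchors).
* BH adjustment is applied per family as described; no hierarchical
  correction across stages.
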