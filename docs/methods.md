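# Methods

## Model and procedure

The tool treats candidate prioritization as a proximity query on a
directed, confidence-weighted PPI graph. The seed set is the deregulated
proteins (DPs) of one case–control proteomic comparison; every other node
is a candidate. Two proximity measures are combined because they capture
complementary notions of closeness: the shortest-path score is purely
metric (few hops to many seeds), while the random walk with restart (RWR)
integrates over all paths and rewards being embedded in seed-dense
regions.

The pipeline runs in four stages:

1. **Raw network.** Directional `protein.actions` records with confidence
   ≥ `min_score` (default 900 on the 0–999 scale — the "highest
   confidence" cutoff; a flag switches to strict `>`) are oriented acting
   protein → acted-on protein. Records flagged directional whose acting
   annotation marks the partner are reversed; directional records without
   any acting annotation keep their stated orientation. Self-interactions
   are dropped and duplicate ordered pairs merged (maximum score kept).
2. **Contextualization.** `+DP` re-injects every directional seed-incident
   record regardless of score (newly added edges are flagged, seeds with
   no directional record at all are reported, never silently dropped).
   `+C` enumerates maximal cliques of the undirected projection
   (direction is ignored inside cliques), resolves overlaps into disjoint
   groups and collapses each group into a super-node whose edges are the
   union of its members' external edges. In `+DP+C`, cliques are by
   default detected after DP injection (injected edges can create
   cliques); a flag flips this order.
3. **Scoring and ranking.** `SP` and `RW` as in the README; candidates are
   ranked by each score descending with competition ("1224") ranking, and
   the rank product `CS = rank_sp · rank_rw` (exact integer) gives the
   final ascending order, ties broken lexicographically by node id so runs
   are bytewise reproducible.
4. **Expansion and evaluation.** Each ranked super-node is replaced by the
   member ranking best in a companion prioritization of the uncollapsed
   network with the same seeds (members absent from that companion ranking
   fall back to lexicographic order); other members are dropped and ranks
   renumbered. Precision at k and its trapezoidal AUC, cross-specificity
   deltas and the overall specificity rank are computed on the expanded,
   protein-level ranking.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_score` | 900 | confidence threshold on the 0–999 scale (≥, "highest confidence") |
| `min_clique_size` | 3 | smallest group kept by clique consolidation |
| `r` | 0.7 | restart probability of the walker |
| `tol` | 1e-10 | L1 convergence threshold of the RWR iteration |
| `max_iter` | 10 000 | iteration cap; exceeding it is an error carrying the residual |
| `k_max` | 100 | precision-curve depth |
| `top_n_reference` | 500 | reference candidates kept per disease, by inference score |

The restart value 0.7 is the method's standard setting; with contraction
factor `1 − r = 0.3` per step the iteration reaches `tol = 1e-10` in a few
dozen iterations, so the cap is never binding in practice.

## Design choices on genuinely open points

* **Unreachable seeds in the SP sum.** The reciprocal-sum formula is only
  defined when every seed is reachable. Default policy: sum over reachable
  seeds only and order candidates primarily by reachable-seed count
  (descending), then by score. This preserves "closer to more seeds is
  better" without inventing a penalty constant; `penalty` (distance
  `|nodes|` per missing seed) and `exclude` (score-only ordering) are
  available behind a flag.
* **Walk direction.** `A` is column-normalized over out-edges, so the
  walker travels along interaction direction (seeds outward), while SP
  distances run candidate → seed. The asymmetry is intentional: the two
  measures probe regulation in both directions.
* **Dangling nodes.** Out-degree-zero columns of `A` are zero; leaked mass
  is not redistributed by default (the restart term keeps the iteration
  contracting), so the probability vector sums to < 1 on graphs with
  dangling nodes. `dangling="restart"` redistributes the leaked mass onto
  `P_0`, restoring a proper distribution.
* **Overlapping cliques.** Maximal cliques overlap heavily; groups are
  made disjoint greedily by decreasing size (ties: lexicographically
  smallest member), keeping a trimmed clique only if `min_clique_size`
  members remain. Any subset of a clique is a clique, so trimmed groups
  stay valid.
* **Seeds and cliques.** Seeds are excluded from clique membership in the
  collapsed variants: both the restart distribution and the SP targets
  need every seed addressable as its own node, which absorption into a
  super-node would break.
* **Clique representative.** "Best-ranked member" needs a reference
  ranking; the companion run on the uncollapsed network with identical
  seeds provides it, and the choice is recorded in the result metadata.

## Synthetic studies

The generator emulates the tool's three inputs at a scale (≤ 200 nodes by
default) where brute-force oracles — per-pair BFS, dense linear solves,
exhaustive clique enumeration — run in seconds. Defaults: 120 proteins,
directed background edge probability 0.04 with confidence scores 900–999,
4 planted cliques of 5–9 members wired near the seeds, 15 seeds, 25
reference candidates. A `planted_overlap_fraction` (default 0.8) of the
reference candidates is wired 1–2 directed hops into a seed plus a
reciprocal seed edge; half of this seed-incident wiring
(`low_confidence_fraction = 0.5`) is scored below the confidence
threshold, which is precisely the information the `+DP` contextualization
recovers, while the seed-adjacent cliques of non-reference proteins are
the clutter that `+C` consolidates out of the top ranks. At overlap
fraction 0 the reference is drawn uniformly and independently of the
topology, so expected precision equals the analytic chance level
`n_reference / (n_nodes − n_seeds)` exactly — the null used by the tests.

What the generator does **not** emulate: STRING's scale-free degree
distribution and hub structure, correlated confidence scores, biological
module overlap beyond literal cliques, and identifier-mapping attrition.
Passing tests therefore demonstrate algorithmic correctness and the
direction of the contextualization benefits on planted structure, not
effect sizes on real interactome data.

## Numerical and determinism notes

* All randomness flows through one seeded NumPy generator per artifact;
  node sets are iterated in sorted order everywhere, so identical inputs
  give byte-identical output files.
* Scores in "real" dialect (0–1) are converted by `round(1000·s)` capped
  at 999.
* The precision AUC integrates over k = 1..K (raw trapezoidal area, as
  only relative comparisons matter); a normalized variant `auc / (K − 1)`
  — the mean curve height — is reported alongside for readability. A
  one-point curve has zero area by convention.
* Tie handling is competition ranking throughout, including the overall
  specificity rank (`1 + #{decoy AUC > specific AUC}`, ties share the
  better rank).
* Test and acceptance simulations use 100 (suite) or 60 (acceptance
  script) study seeds at the default 120-node scale, and precision depth
  k ≤ 50 — at 25-entry reference lists, deeper curves only dilute both
  signal and null identically.

## Known limitations

* Reproducing the published full-interactome statistics (353,643 edges /
  6,391 proteins; 265 cliques / 3,569 proteins; 21,051 edges / 3,109
  collapsed nodes) requires the external STRING v10.5 download; the
  published node arithmetic itself leaves a 22-node gap
  (6391 − 3569 + 265 = 3087 ≠ 3109), so the reproduction sweep
  (`--min-score`, `--strict-greater`, `--min-clique-size`) should report
  both its best-matching settings and the residual discrepancy rather
  than force agreement.
* Edge confidence is used only for thresholding; the walk and the
  distances are unweighted.
* Identifier mapping is as good as the supplied alias table; unmapped
  seeds are reported but cannot contribute signal.
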