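# Methods

## Problem and pipeline

`ppanet` reconstructs stage-resolved protein–protein association networks
for a curated signalling system. Four steps:

1. **Protein pool.** A roster of proteins, each carrying one pathway
   catalogue out of five: TNF, IL-1, MyD88-dependent TLR-4,
   MyD88-independent TLR-4, negative regulators. The packaged roster has
   60 proteins (21 TNF, 8+8+8 across IL-1/TLR-4, 15 negative regulators).
   Symbols are matched case-insensitively and reported upper-case; Greek
   letters are transliterated (α→A, β→B, γ→G, ε→E) so plain-text edge
   lists and the roster agree on one spelling.
2. **Rough network.** Candidate edges from two-column (BioGRID-like) and
   scored three-column (STRING-like) tab-delimited exports are merged,
   induced on the pool, and deduplicated with provenance unioned. The
   STRING-like combined-score threshold defaults to 0.4 — the usual
   "medium confidence" convention, as no principled value exists —
   and is overridable. The rough network is undirected: databases record
   associations, not regulation direction.
3. **Dynamic refinement.** Per stage window and per target, constrained
   least squares + model-order selection prune the candidate neighbourhood
   (details below).
4. **Cross-talk ranking.** CTRV/link counting over the refined stage
   networks, stage-wise rankings, and bow-tie core selection.

## The dynamic model and its two modes

Protein abundance follows the linear update

    y_p[t+1] = y_p[t] + Σ_q b_pq y_q[t] + α_p x_p[t] − β_p y_p[t] + ω_p[t]

with ω_p[t] ~ N(0, σ_p²) i.i.d. The model is fit independently per target
and per stage window, over the window's transitions (a 5-point window
yields N = 4 regression rows).

**Full mode** (distinct protein and mRNA tracks, available for synthetic
data): the unit coefficient on y_p[t] is absorbed into the response, so the
regression is Δy_p[t] on {x_p[t], −y_p[t], y_q[t]…} with bounds α_p ≥ 0 and
β_p ∈ [0, 1]; b_pq are unconstrained (associations may be inhibitory). The
sign convention makes every constrained coefficient nonnegative. Keeping
y_p[t] as a free column instead would be exactly collinear with −y_p[t] and
destroy the identifiability of α and β; fixing its coefficient at 1 is what
the model equation states.

**Proxy mode** (default for microarray input, where protein abundance is
unobserved): measured mRNA stands in for protein, making translation and
degradation unidentifiable separately; they collapse into one unconstrained
self-coefficient a_p = 1 + α_p − β_p, and the regression is y_p[t+1] on
{y_p[t], y_q[t]…}. When the protein and mRNA tracks coincide, a full-mode
fit returns a confounded (α̂, β̂) pair whose combination 1 + α̂ − β̂ equals
the proxy self-coefficient — a property the tests check.

There is no intercept column: the update has none.

## Constrained least squares

`scipy.optimize.lsq_linear` solves the box-constrained problem (BVLS for
full-rank systems, the trust-region reflective solver when rank-deficient).
Systems with no finite bounds use the exact minimum-norm `lstsq` solution,
with a degeneracy flag when the design is rank-deficient. Fitting is fully
deterministic.

## Model-order selection

For each target the candidate orders are k = 0..k_max with
k_max = min(Q, N − c − 1), where c is the number of always-included self
columns (1 in proxy mode, 2 in full mode) — the model must leave at least
one residual degree of freedom. Order k is scored by

    AIC(k) = N ln(RSS_k / N) + 2 (k + c) + 2 (k + c)(k + c + 1) / (N − k − c − 1)

i.e. Gaussian-likelihood AIC with the standard small-sample correction
(AICc); stage windows supply very few transitions, and without the
correction the criterion over-selects badly — on planted 20-protein
networks it accepted roughly half of all decoy candidates, collapsing edge
precision to ~0.5. `corrected=False` restores the plain 2(k + c) penalty.
RSS/N is floored at 1e-12 inside the logarithm so exact fits stay finite;
ties go to the smaller order.

Within each order, the best subset is found **exhaustively** when the
neighbourhood has at most 12 candidates (the combinatorics stay small
because k_max caps subset size), and otherwise by the nested prefixes of a
**greedy forward-selection** ordering (each step adds the candidate with
the largest RSS drop, ties to the smaller symbol). A one-shot ranking of
candidates by |b̂| from the largest feasible model was evaluated and
rejected: near-saturated fits produce unstable rankings, measurably
degrading recovery of planted networks.

The association (q, p) is retained iff q is in the target's selected set;
directed selections are symmetrised into undirected edges annotated
`q->p`, `p->q` or `both`. Nodes of a refined network are the non-isolated
proteins. With the study's 5-point windows (N = 4), k_max ≤ 2 in proxy
mode and the corrected criterion is very conservative — a faithful
limitation of such short windows; recovery benchmarks use denser 10-point
windows.

## Time grid and stages

The canonical design samples 0–8 h at 15-min spacing up to 4 h and 30-min
spacing thereafter (25 points): this is the only allocation of "15 or 30
minute" sampling that yields 25 points with the stated stage structure.
Stage boundaries {1, 2, 3, 4, 6, 8} h split the grid into six windows of
five points; adjacent windows share the boundary sample (6 stages × 5
points = 30 > 25 forces sharing). Probe-level matrices are collapsed to
one row per symbol by maximal variance across the grid (ties to the
lexicographically smallest probe id — deterministic and favouring
responsive probes). Expression is used on the log2 scale as provided; no
further normalisation is applied inside fitting.

## Cross-talk ranking

Per stage, a protein's link contribution is its degree in that stage's
refined network; its CTRV contribution is the number of incident edges
whose partner has a different pathway class. Totals sum over stages.
Identities that must (and do, by test) hold: CTRV ≤ link per protein;
Σ link = 2 × Σ edges; Σ CTRV = 2 × (cross-class edges); relabelling all
proteins into one class zeroes every CTRV.

Design choices: proteins in several pathways are assigned to the
earliest-activated one under the stimulus (TNF, then IL-1, then
MyD88-dependent, then MyD88-independent TLR-4) because multi-assignment
dilutes the CTRVs of genuine bridges; negative regulators form their own
class so their edges count as cross-pathway; edges annotated `both`
count once per endpoint per stage (CTRV is defined on associations, not
directed regulations); ranking ties break by link descending then symbol
ascending (a convention — any fixed order would do). The bow-tie export
labels a packaged receptor list (TNFR1, TNFR2, IL1R1, IL1R2, TLR4, ST2L)
as the input side, the top-k CTRV proteins as the core.

## Synthetic-data generator

The generator plants a directed coefficient network over labelled
proteins and iterates the update model forward.

* **Topology.** The directed edge count is Binomial(n(n−1), density);
  round(fraction·M) edges are drawn from cross-class ordered pairs and the
  rest from within-class pairs, so the realised cross-class fraction
  tracks the request. Coefficient magnitudes are uniform in (0.3, 0.9)
  with random signs.
* **Stability.** Planted coefficients are shrunk (×0.9 repeatedly) until
  the spectral radius of the linear update I + B − diag(β) is below 1.05,
  preventing overflow on 25-step grids; a hard overflow guard aborts
  divergent simulations with advice to reduce coefficients.
* **Rates.** α_p ~ U(0.4, 0.9) and β_p ~ U(0.2, 0.8): translation is the
  dominant drive of protein change, as in cells, where new protein comes
  mostly from the mRNA pool. This choice is also what keeps the benchmark
  identifiable — when interactions dominate, all protein tracks collapse
  onto shared dynamical modes and no method can attribute edges.
* **mRNA driver.** Default tracks are pulse-and-decay curves
  (base + amp·(t/τ)·e^(1−t/τ)) with per-protein peak times spread over the
  whole observation span, plus a low-order sinusoidal fluctuation —
  transcriptional programs differ gene to gene, and near-identical inputs
  would make the system unidentifiable by design. Constant or user-supplied
  drivers are accepted.
* **Noise** is Gaussian inside the update — the same place the fitting
  model puts its residual.

What the generator does **not** emulate: mass-action/Hill kinetics,
replicate or batch structure, probe-level effects, missing data, and the
heavy-tailed noise of real microarrays. Passing recovery tests therefore
demonstrates correctness of the identification machinery under the model's
own assumptions, not performance on real arrays.

## Benchmarks and problem sizes

Recovery experiments use 20 proteins, 4 classes, planted density 0.08,
full mode, a single 10-point window, and a candidate network equal to the
symmetrised truth plus an equal number of decoy edges (decoy_fraction = 1),
so that precision is informative. Across seeds 1–5 at σ = 0.05 the mean
undirected-edge F1 is ≈ 0.83 with mean coefficient RMSE ≈ 0.095, and mean
F1 degrades monotonically as σ rises through 0.2 and 0.5 — numbers the
acceptance script recomputes. Model selection agrees with exhaustive
subset search on all 200 randomly generated ≤4-candidate systems tested.

## Known limitations

* Real-data stage windows provide only 4 transitions per fit; at most one
  or two interactors per target per stage can be supported, so refined
  networks on real input are sparse relative to the candidate set.
* The method identifies associations compatible with the linear update on
  expression proxies; it cannot distinguish direct binding from shared
  regulation, and direction annotations reflect regression structure, not
  causal direction.
* Database snapshots evolve; edge counts from current BioGRID/STRING
  exports will not match any particular historical analysis.
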