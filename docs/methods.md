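# Methods

This note documents the models implemented in `rhizomod`, the conventions
adopted where a published verbal description leaves the mathematics open,
and what the synthetic-data tests do and do not establish about real data.

## Constraint-based model of non-growing bacteroids

The metabolic state is a flux vector `v` over the reconstruction's
reactions satisfying steady state, `S·v = 0`, and per-reaction bounds
`α_j ≤ v_j ≤ β_j` (thermodynamic/enzymatic constraints; reversibility is
encoded in the bounds, never in `S`). Because nitrogen-fixing bacteroids do
not grow, the phenotype is represented not by a biomass reaction but by an
objective `Z = Σ_i c_i·v_i` over *drain* fluxes of key metabolites. Each
objective component is realised as an irreversible sink reaction
(metabolite → ∅, bounds 0–1000) attached on demand; the original
reconstruction is never mutated. All weights `c_i` default to 1.

The default nitrogen-fixation objective has 16 unit-weight components:
a literature-derived core (glycogen, histidine, lysine,
polyhydroxybutyrate, valine, plus alanine, aspartate and ammonium exported
to the plant, tagged `[e]`) and eight metabolome-derived additions (malate,
tryptophan, arginine, citrate, CMP, fumarate, 3-phosphoglycerate,
2-oxoglutarate, tagged `[c]`). The narrative account of the refinement
names nine new candidates (it lists aspartate a second time, as a cytosolic
species next to the exported one); we keep the 16-species composition and
note the discrepancy here rather than invent a seventeenth component.

Flux units are carried opaquely as "model flux units" (the source material
prints two different unit strings for the same 0–20 uptake scale); no
conversion is attempted.

### Degeneracy and the parsimonious stage

LP optima on metabolic networks are routinely degenerate: many flux
distributions achieve the same `Z`, and the *active subnetwork* (reactions
with `|v| > ε`) would then depend on solver internals. `solve_fba`
therefore, by default, solves a second LP that fixes the optimal `Z`
(within a relative tolerance of 1e-9) and minimises `Σ_j |v_j|`,
linearised with auxiliary variables `t_j ≥ |v_j|`. This parsimonious
post-processing is this package's own choice — reported subnetworks become
reproducible across runs and solvers — and can be disabled with
`parsimonious=False`. The active-flux threshold is `ε = 1e-6` model flux
units: above HiGHS feasibility tolerances, far below biological fluxes on
the 0–20 uptake scale. Both LPs are solved with `scipy.optimize.linprog`
(HiGHS); infeasibility and unboundedness are reported in the solution
status, never as silent zeros.

### Phase planes and the diagonal scan

`phenotype_phase_plane` caps the magnitude of two exchange fluxes
(exchanges are oriented so uptake is the positive direction) on a grid —
by default 21 integer caps spanning 0–20 — and records the optimal `Z`
per cell; infeasible cells are NaN. `diagonal_scan` applies `n` equally
spaced caps (default 20, endpoints inclusive) to both exchanges
simultaneously from 20 down to 0, emulating the simultaneous withdrawal of
two carbon sources, and extracts the active subnetwork at each condition.

## Differential metabolomics and objective refinement

Each metabolite carries triplicate relative peak areas per condition
(dimensionless, internal-standard normalised). A condition counts as
detected only with all three replicates present; metabolites seen in one
condition only are flagged (`bac_only` / `vl_only`) and excluded from
testing — they remain visible in outputs for manual consideration, since
no p-value can be attached to them at n = 3 vs 0.

For both-condition metabolites the effect size is
`log₂(mean(bac)/mean(vl))` on the raw areas, and significance comes from a
one-sided two-sample Welch *t*-test on log₂-transformed replicates
(alternative: enrichment during nitrogen fixation). Welch rather than the
pooled-variance test because equal variances cannot be assessed at n = 3;
log transform because multiplicative lognormal noise is the natural error
model for relative peak areas. Degenerate zero-variance cases resolve to
p = 1 when the groups coincide and p = 0 when they are separated constants.
No multiple-testing correction is applied — the published gate is a raw
p < 0.01 — and selection additionally requires fold ≥ 2 (we read
"increased at least 2-fold" as a ratio threshold, the only reading
consistent with the accompanying "ratio higher than 2"). Candidates are
ordered by decreasing log-ratio: the sequential acceptance below has no
published order, and strongest-signal-first is reproducible.

### The one-third retention rule

Accepted candidates must not collapse the phenotype. A subtlety: adding a
*free* drain to a maximised objective can never lower the optimum nor make
the LP infeasible, so a literal "augment and compare" test would accept
every candidate vacuously. The audit therefore demands that the candidate
actually be produced: its sink receives a lower bound of `min_drain`
(default 1.0 model flux units, roughly 5% of a full 20-unit uptake) during
the probe. A candidate is kept iff that probe LP is feasible and bounded
— unproducible metabolites (blocked pathways) fail here — and its optimum
stays at or above `of_retention = 1/3` of the previous accepted
objective's optimum. The comparison baseline is cumulative (the
immediately preceding accepted objective, not the original base), and the
final reported objective keeps only the component, not the forced bound.

## Structural modules from the metabolite graph

Reactions are projected to an undirected graph: every (reactant, product)
pair of each reaction becomes an edge — never reactant–reactant or
product–product pairs — identical for reversible and irreversible
reactions. Thirty currency species (phosphate, protons, water, O₂, CO₂,
N₂, NH₃/NH₄, NAD(P)(H), FAD(H₂), ferredoxins, acetyl-CoA, PPi, H₂O₂,
fructose-1,6-bisphosphate, and the exported alanine/glutamate pool) are
excluded before projection; the list is reproduced as printed, including
the phosphorylated sugar, and is overridable. The graph is simple —
duplicate edges collapse, with contributing reaction ids kept as edge
provenance. Species appearing on both sides of one reaction are
net-summed; a net-zero species generates no edges for that reaction.

Closeness of a metabolite pair is the association `A_ij = 1/d_ij²` with
`d_ij` the unweighted shortest path length: near neighbours are amplified,
remote pairs damped. Conventions where the formula is silent: `A_ii = 1`
(1/0² is undefined) and `A_ij = 0` for disconnected pairs (the d → ∞
limit). Each metabolite is described by its row of `A`; rows `i` and `j`
are compared by Kendall's τ-b after dropping positions `i` and `j` from
both rows, so the self-closeness convention never dominates the rank
correlation, and the tie correction matters because path lengths are
heavily tied. Identical rows get distance 0 by definition; an undefined τ
(a fully tied row carries no rank signal) maps to distance 1. The
resulting `1 − τ ∈ [0, 2]` distances are clustered by average-linkage
agglomeration (`scipy.cluster.hierarchy`); determinism is guaranteed by
fixing the node order fed to the linkage (the model's metabolite order).
The tree is cut either at a fixed `k` (default 9, the module count
reported for the full reconstruction — the published cut criterion itself
is unstated) or at the largest gap between consecutive merge heights
(`cut="max_gap"`). Labels are renumbered 1..k by first appearance in node
order, making the output equivariant under relabeling.

Modules are characterised two ways: class composition (fractions of
nucleic-acid / peptide / lipid members among classified members;
unclassified counted separately) and metabolome coherence (the fraction of
metabolome-matched members with positive log-ratio; undefined, not zero,
for modules with no matched member).

## Consistency and overlap scores

The consistency coefficient restricts the predicted-active gene (enzyme)
set to the union of a fixed pathway scope and reports
`η = |predicted ∩ detected| / |predicted|`, pooled over pathways. Pooling
(rather than averaging per-pathway ratios) is adopted because it makes η
identically the detected/total coverage ratio, which is how the published
coefficient and coverage figures agree with each other (e.g. 187/306 ≈
0.61); per-pathway values and the three-way breakdown
(predicted-not-detected / both / detected-not-predicted) are reported
alongside. An empty scoped prediction leaves η undefined and flagged —
never silently 0.

The overlapping coefficient between two active subnetworks is computed on
metabolite (node) sets, as the verbal definition counts metabolites:
`Ω = common / (only_i + only_j + common)`, i.e. the Jaccard index — the
unique simple form matching the stated 0-to-1 range. Conventions:
`Ω(∅, ∅) = 1`, `Ω(∅, X) = 0`.

## The synthetic study

The generator emulates the structure, not the biochemistry, of the real
inputs. A toy reconstruction has `n_modules` blocks of `mets_per_module`
cytosolic metabolites each: a spanning chain of 1:1 conversions guarantees
producibility, extra intra-module reactions (drawn as distinct non-chain
pairs before any repeats) densify each block towards a clique, and
consecutive blocks are joined by single bridge reactions. Exchange
reactions feed the first block; objective components are the terminal
metabolites of the last blocks, so every component is reachable by
construction and the maximal objective equals total uptake (unit
stoichiometry throughout). An optional constitutive feed (`lb = ub > 0`)
creates the stable fed core used in robustness experiments. One gene, one
enzyme and one pathway label per reaction — no isozymes — so the expected
consistency coefficient equals the planted detection rate exactly.

Metabolome tables draw baselines log-uniformly over two decades (CE-MS
relative areas span orders of magnitude) and multiply by unit-mean
lognormal noise with coefficient of variation `noise_cv` (default 0.25, a
realistic replicate CV for relative peak areas); planted metabolites get
an exact mean fold of `fold` (default 4, comfortably above the 2-fold
gate), and condition-exclusive species are drawn outside the planted set
so they never entangle the t-test ground truth. Detection sets include
each truly active gene/enzyme with probability `ht_tpr` (default 0.7,
in the range of real transcriptome/proteome coverage) and each inactive
one with probability `ht_fpr` (default 0). All generators are pure
functions of their spec, including its seed.

What passing synthetic tests shows: the statistics, the clustering, the LP
machinery and the scoring recover planted truth under the stated noise
models. What they do not show: correctness of any particular curated
reconstruction, robustness to non-lognormal noise, isozyme/GPR logic
(flat gene sets only, by design), or m/z identification errors upstream of
the metabolome table.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale by design:
toy reconstructions of 15–40 metabolites (three 5-metabolite clique
blocks for module recovery; four 10-metabolite blocks, ~225 reactions,
for the 200-gene consistency experiment), 400-metabolite synthetic
metabolomes, 6×6 phase-plane grids in tests (21×21 remains the pipeline
default), and 20-point diagonal scans. LP agreement is checked against
brute-force vertex enumeration on random models of at most 8 reactions,
where enumeration is exact and fast. Feasibility tolerances: steady-state
residuals ≤ 1e-6; oracle agreement to 1e-6; the parsimonious stage
re-imposes optimality within 1e-9 relative.

## Known limitations

- No flux variability analysis, MOMA, dynamic FBA or integer constraints;
  alternate optima are handled only through the parsimonious stage.
- Gene–protein–reaction boolean logic is out of scope; gene/enzyme
  annotations are flat sets.
- The module count k = 9 for real reconstructions is reproducible only
  modulo the unpublished dendrogram cut criterion; the `max_gap` rule is
  offered as a principled alternative.
- The `min_drain` probe magnitude in objective refinement is a convention;
  results for candidates near the one-third boundary can depend on it.
- XLSX supplements are not parsed; real reconstructions are consumed via a
  one-time export to the canonical table (or SBML).
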