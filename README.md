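# rhizomod

Structural modules, metabolome-driven objective functions and optimal
phenotypes in genome-scale metabolic networks.

`rhizomod` is a tested, reusable implementation of an integrative
systems-biology analysis built around symbiotic nitrogen fixation in
rhizobia: bacteroids inside legume root nodules do not grow, so their
metabolic phenotype is modelled not as biomass production but as the
sustained drain of a set of key metabolites (amino acids, TCA-cycle
intermediates, storage polymers, ammonium exported to the host plant). The
package chains five stages:

1. **Reconstruction handling** (`network_model`) — parse a reaction table
   (or SBML) into a validated model, expose the stoichiometric matrix *S*,
   and project reactions into an undirected metabolite graph by linking each
   reactant to every product, with a 30-species currency exclusion list
   (ATP, water, protons, NAD(P)H, ...) so cofactor hubs do not
   short-circuit path lengths.
2. **Flux balance analysis** (`optimization`) — maximise the
   nitrogen-fixation objective Z = Σᵢ cᵢ·vᵢ over drain fluxes subject to
   steady state (S·v = 0) and bounds (αⱼ ≤ vⱼ ≤ βⱼ), with an optional
   parsimonious second stage (fix Z, minimise Σ|v|) so the *active
   subnetwork* — the reactions with |v| above a threshold — is a
   reproducible fingerprint of the condition. Phenotype phase planes sweep
   two uptake caps over a grid; the diagonal scan reduces both carbon
   sources simultaneously.
3. **Differential metabolomics** (`metabolome_of`) — triplicate CE-MS
   relative peak areas under two conditions are compared by a one-sided
   Welch *t*-test on log₂ replicates; metabolites with fold ≥ 2 and
   p < 0.01 become objective candidates, and each is kept only if the
   network can actually produce it at steady state without cutting the
   audited optimum below one third of the previous objective value.
4. **Module detection** (`topology`) — closeness between metabolites is
   1/d², the inverse square shortest-path length; rows of that association
   matrix are compared with Kendall's τ-b and clustered by average-linkage
   agglomeration; modules are then characterised by functional class
   composition (nucleic acids / peptides / lipids) and by the coherence of
   their members' metabolome response.
5. **Assessment** (`assessment`) — the consistency coefficient η is the
   fraction of genes (enzymes) predicted active in silico, within a fixed
   pathway scope, that high-throughput experiments detected; the
   overlapping coefficient Ω = |i∩j| / |i∪j| compares the metabolite sets
   of two active subnetworks and quantifies robustness across conditions.

A first-class synthetic-data generator (`synthetic`) plants ground truth
for every stage — graph modules as dense reaction blocks joined by single
bridges, lognormal triplicate noise with planted fold-changes, detection
sets with a controlled true-positive rate — so the whole pipeline is
verifiable end to end without any external download.

## Worked example

```python
import numpy as np
from rhizomod import (SyntheticSpec, generate_toy_model, solve_fba,
                      project_metabolite_graph, shortest_path_matrix,
                      association_matrix, detect_modules, diagonal_scan,
                      overlap_matrix)

spec = SyntheticSpec(n_modules=3, mets_per_module=5, intra_reactions=10,
                     n_bridges=2, n_exchange=2, constitutive_uptake=5.0,
                     seed=1)
model, planted, objective = generate_toy_model(spec)
print(f"reconstruction: {len(model.reactions)} reactions, "
      f"{len(model.metabolites)} metabolites")

for exchange in ("EX_0", "EX_1"):          # cap both carbon uptakes at 20
    model.reaction(exchange).upper_bound = 20.0
solution = solve_fba(model, objective)
print(f"FBA: status={solution.status}, Z={solution.objective_value:.1f}")

graph = project_metabolite_graph(model)
nodes, D = shortest_path_matrix(graph)
partition = detect_modules(association_matrix(D), nodes, k=3)
recovered = all((partition.assignment[n] == partition.assignment[m])
                == (planted[n] == planted[m])
                for n in nodes for m in nodes)
print(f"modules: k={partition.k}, planted blocks recovered: {recovered}")

points = diagonal_scan(model, objective, "EX_0", "EX_1",
                       n_points=20, hi=20.0, lo=0.0)
zs = [p.solution.objective_value for p in points]
print(f"diagonal scan: Z from {zs[0]:.1f} down to {zs[-1]:.1f}")
labels, omega = overlap_matrix([p.subnetwork for p in points])
off = omega[~np.eye(len(points), dtype=bool)]
print(f"subnetwork overlap: min={off.min():.2f}, "
      f"extreme points={omega[0, -1]:.2f}")
```

prints

```
reconstruction: 35 reactions, 15 metabolites
FBA: status=optimal, Z=45.0
modules: k=3, planted blocks recovered: True
diagonal scan: Z from 45.0 down to 5.0
subnetwork overlap: min=0.80, extreme points=0.80
```

Every toy conversion is 1:1, so at full caps the optimum equals total
uptake (20 + 20 + 5 constitutive = 45). As both carbon sources shrink to
zero, the objective falls to the constitutive feed's 5 — yet the active
subnetwork barely changes: the minimum pairwise overlap along the 20
conditions stays at 0.80. A reduced phenotype comes from reduced flux, not
from a broken network structure, which is the central robustness claim the
pipeline quantifies.

The same analysis runs from the shell, driven by a YAML config whose
defaults are the study settings (fold ≥ 2, p < 0.01, one-third retention,
uptake range 0–20, 20 scan points, k = 9 modules):

```sh
rhizomod init-config cfg.yaml
rhizomod run --config cfg.yaml --stage all
```

Stages: `simulate`, `fba`, `refine-of`, `modules`, `phase-plane`,
`assess`, `report` — each writes TSV/GraphML artifacts and a JSON manifest
under the output directory. Real reconstructions are consumed as a
canonical table (columns `reaction_id, name, equation, lower_bound,
upper_bound, genes, enzymes, pathways`, arrows `->` / `<=>`) or as SBML;
metabolome tables, name maps, detection sets, pathway scopes and
functional annotations are plain TSV/text, as documented in
`docs/methods.md`.

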