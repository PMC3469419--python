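"""Synthetic study inputs with planted ground truth.

Every pipeline stage can be exercised without the original supplementary
datasets: this module generates (1) a toy reconstruction whose metabolite
graph has planted modules — dense intra-module reaction blocks joined by a
controlled number of bridge reactions — fed by exchange reactions and ending
in known objective components; (2) a triplicate metabolome table with
lognormal replicate noise, planted fold-changes and condition-exclusive
species; (3) detection sets that include each truly active gene/enzyme with a
controlled true-positive rate.  All generators are pure functions of their
spec (including its seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .metabolome_of import REPLICATES, MetabolomeRecord
from .network_model import MetabolicModel, Reaction
from .optimization import ObjectiveFunction

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "SyntheticSpecError",
    "generate_toy_model",
    "generate_metabolome",
    "generate_ht_sets",
    "planted_annotation",
]


class SyntheticSpecError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults mirror the real study's shape at toy scale: triplicate
    conditions, a 2-fold-gated differential signal planted at 4-fold, a
    detection true-positive rate in the range of high-throughput coverage,
    and uptake caps on the 0-20 flux scale used throughout.
    """

    n_modules: int = 3
    mets_per_module: int = 6
    intra_reactions: int = 9      # per module, >= chain length (mets-1)
    n_bridges: int = 2            # total inter-module reactions, >= n_modules-1
    n_exchange: int = 2           # uptake reactions feeding module 1
    of_size: int = 2              # drained objective components, <= n_modules
    planted_up: tuple[str, ...] | None = None  # None -> generator picks
    n_planted_up: int = 5
    fold: float = 4.0
    noise_cv: float = 0.25
    replicates: int = REPLICATES
    n_exclusive_bac: int = 2
    n_exclusive_vl: int = 2
    ht_tpr: float = 0.7
    ht_fpr: float = 0.0
    constitutive_uptake: float = 0.0  # fixed extra feed into module 1 (flux units)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name in ("n_modules", "mets_per_module", "intra_reactions",
                     "n_bridges", "n_exchange", "of_size"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if self.mets_per_module >= 2 and self.intra_reactions < self.mets_per_module - 1:
            problems.append("intra_reactions must cover the module chain "
                            f"(>= {self.mets_per_module - 1})")
        if self.n_modules > 1 and self.n_bridges < self.n_modules - 1:
            problems.append("n_bridges must connect all modules "
                            f"(>= {self.n_modules - 1})")
        if self.of_size > self.n_modules:
            problems.append("of_size exceeds the number of modules with a "
                            "guaranteed-producible terminal metabolite")
        if self.noise_cv < 0:
            problems.append("noise_cv must be >= 0")
        if not (0 <= self.ht_tpr <= 1 and 0 <= self.ht_fpr <= 1):
            problems.append("ht_tpr and ht_fpr must lie in [0, 1]")
        if self.replicates != REPLICATES:
            problems.append(f"replicates must be {REPLICATES} (triplicate design)")
        if problems:
            raise SyntheticSpecError("; ".join(problems))


def _module_met(k: int, i: int) -> str:
    return f"m{k}_{i}[c]"


def generate_toy_model(spec: SyntheticSpec
                       ) -> tuple[MetabolicModel, dict[str, int], ObjectiveFunction]:
    """Toy reconstruction with planted graph modules.

    Module k (k = 1..K) is a chain m_k_0 -> ... -> m_k_{p-1} densified with
    extra random intra-module reactions; consecutive modules are linked by a
    bridge from the chain end of one to the chain head of the next (extra
    bridges between random module pairs).  Exchange reactions feed the first
    metabolites of module 1, so every chain head — and hence every terminal
    objective component — is producible at steady state by construction.
    One gene, one enzyme and one pathway label are assigned per reaction.

    Returns (model, planted partition metabolite->module, base objective).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    K, p = spec.n_modules, spec.mets_per_module
    reactions: list[Reaction] = []

    def _rxn(rid: str, stoich: dict[str, float], pathway: str,
             lb: float = 0.0, ub: float = 1000.0) -> Reaction:
        idx = len(reactions)
        return Reaction(id=rid, stoichiometry=stoich, reversible=False,
                        lower_bound=lb, upper_bound=ub,
                        genes=frozenset({f"g{idx:03d}"}),
                        enzymes=frozenset({f"e{idx:03d}"}),
                        pathways=frozenset({pathway}))

    partition: dict[str, int] = {}
    for k in range(1, K + 1):
        for i in range(p):
            partition[_module_met(k, i)] = k
        for i in range(p - 1):
            reactions.append(_rxn(f"R{k}_chain{i}",
                                  {_module_met(k, i): -1.0, _module_met(k, i + 1): 1.0},
                                  pathway=f"module{k}"))
        extra = spec.intra_reactions - (p - 1)
        # densify with distinct non-chain pairs first (so a high intra count
        # drives the block towards a clique), repeating only once exhausted
        non_chain = [(a, b) for a in range(p) for b in range(a + 1, p)
                     if b != a + 1]
        pool: list[tuple[int, int]] = []
        while non_chain and len(pool) < extra:
            batch = [non_chain[i] for i in rng.permutation(len(non_chain))]
            pool.extend(batch)
        for made, (a, b) in enumerate(pool[:extra]):
            reactions.append(_rxn(f"R{k}_x{made}",
                                  {_module_met(k, int(a)): -1.0,
                                   _module_met(k, int(b)): 1.0},
                                  pathway=f"module{k}"))

    # bridges: a backbone connecting consecutive modules, then extras
    bridge_pairs = [(k, k + 1) for k in range(1, K)]
    extra_bridges = spec.n_bridges - len(bridge_pairs)
    while extra_bridges > 0 and K > 1:
        a, b = sorted(rng.choice(np.arange(1, K + 1), size=2, replace=False))
        bridge_pairs.append((int(a), int(b)))
        extra_bridges -= 1
    for idx, (a, b) in enumerate(bridge_pairs):
        reactions.append(_rxn(f"Rbridge{idx}",
                              {_module_met(a, p - 1): -1.0, _module_met(b, 0): 1.0},
                              pathway="bridge"))

    for j in range(spec.n_exchange):
        reactions.append(_rxn(f"EX_{j}", {_module_met(1, j % p): 1.0},
                              pathway="exchange"))
    if spec.constitutive_uptake > 0:
        reactions.append(_rxn("EX_CONST", {_module_met(1, 0): 1.0},
                              pathway="exchange",
                              lb=spec.constitutive_uptake,
                              ub=spec.constitutive_uptake))

    model = MetabolicModel.from_reactions(reactions)
    # objective: terminal chain metabolites of the last of_size modules — the
    # farthest-downstream species, producible through the bridge backbone
    of_modules = list(range(K, K - spec.of_size, -1))
    of = ObjectiveFunction({_module_met(k, p - 1): 1.0 for k in of_modules},
                           label="Z_toy")
    logger.info("generated toy model: %d reactions, %d metabolites, %d modules",
                len(model.reactions), len(model.metabolites), K)
    return model, partition, of


def default_planted_up(spec: SyntheticSpec, names: list[str]) -> tuple[str, ...]:
    rng = np.random.default_rng(spec.seed + 1)
    n = min(spec.n_planted_up, len(names))
    return tuple(sorted(str(x) for x in rng.choice(names, size=n, replace=False)))


def generate_metabolome(metabolite_names, spec: SyntheticSpec
                        ) -> tuple[list[MetabolomeRecord], dict]:
    """Noisy triplicate peak areas over the given metabolite names.

    Baselines are log-uniform over two decades (CE-MS relative areas span
    orders of magnitude); replicates are multiplicative-lognormal with
    coefficient of variation ``noise_cv`` and unit mean, so at noise_cv = 0
    every planted metabolite has an exact fold-change of ``spec.fold``.
    Condition-exclusive metabolites are drawn outside the planted set.

    Returns the records and a truth dict (planted_up, exclusives).
    """
    names = list(metabolite_names)
    spec.validate()
    rng = np.random.default_rng(spec.seed + 2)
    planted = (default_planted_up(spec, names) if spec.planted_up is None
               else tuple(spec.planted_up))
    unknown = sorted(set(planted) - set(names))
    if unknown:
        raise SyntheticSpecError(f"planted_up not among metabolites: {unknown}")

    non_planted = [n for n in names if n not in planted]
    n_excl = spec.n_exclusive_bac + spec.n_exclusive_vl
    if n_excl > len(non_planted):
        raise SyntheticSpecError("not enough non-planted metabolites for "
                                 "exclusive detections")
    excl = ([str(x) for x in rng.choice(non_planted, size=n_excl, replace=False)]
            if n_excl else [])
    bac_only = set(excl[:spec.n_exclusive_bac])
    vl_only = set(excl[spec.n_exclusive_bac:])

    sigma = np.sqrt(np.log1p(spec.noise_cv ** 2))

    def _reps(mean: float) -> tuple[float, ...]:
        if sigma == 0:
            return (mean,) * spec.replicates
        z = rng.standard_normal(spec.replicates)
        return tuple(mean * np.exp(sigma * z - sigma ** 2 / 2.0))

    records = []
    for name in names:
        baseline = 10.0 ** rng.uniform(2.0, 4.0)
        ion_mode = "cation" if rng.random() < 0.5 else "anion"
        fold = spec.fold if name in planted else 1.0
        bac = _reps(baseline * fold)
        vl = _reps(baseline)
        if name in bac_only:
            vl = ()
        elif name in vl_only:
            bac = ()
        records.append(MetabolomeRecord(metabolite=name, ion_mode=ion_mode,
                                        bac=bac, vl=vl))
    truth = {"planted_up": sorted(planted),
             "bac_only": sorted(bac_only), "vl_only": sorted(vl_only)}
    return records, truth


def generate_ht_sets(model: MetabolicModel, active_genes: set[str],
                     ht_tpr: float, fpr: float = 0.0, seed: int = 0
                     ) -> tuple[set[str], set[str]]:
    """Synthetic transcriptome/proteome detection sets.

    Each truly active gene enters the gene set with probability ``ht_tpr``;
    each inactive gene with probability ``fpr``.  Enzymes are sampled
    independently at the same rates over the enzymes of the same reactions
    (one gene and one enzyme per synthetic reaction, so the expected
    consistency coefficient equals ht_tpr when fpr = 0).
    """
    rng = np.random.default_rng(seed)
    active_enzymes = set()
    for rxn in model.reactions:
        if rxn.genes & active_genes:
            active_enzymes |= rxn.enzymes
    genes_out: set[str] = set()
    enzymes_out: set[str] = set()
    all_genes = sorted({g for r in model.reactions for g in r.genes})
    all_enzymes = sorted({e for r in model.reactions for e in r.enzymes})
    for g in all_genes:
        prob = ht_tpr if g in active_genes else fpr
        if rng.random() < prob:
            genes_out.add(g)
    for e in all_enzymes:
        prob = ht_tpr if e in active_enzymes else fpr
        if rng.random() < prob:
            enzymes_out.add(e)
    return genes_out, enzymes_out


def planted_annotation(partition: dict[str, int]) -> dict[str, str]:
    """Functional class per metabolite, cycling the three classes by module
    (module 1 -> nucleic_acid, 2 -> peptide, 3 -> lipid, 4 -> nucleic_acid...)."""
    from .topology import FUNCTIONAL_CLASSES
    return {met: FUNCTIONAL_CLASSES[(module - 1) % len(FUNCTIONAL_CLASSES)]
            for met, module in partition.items()}


def truth_to_json(path, **truth) -> None:
    def _default(obj):
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        raise TypeError(f"not JSON serialisable: {type(obj)}")
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=_default)
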