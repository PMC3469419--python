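"""Model assessment: consistency with detection sets and subnetwork overlap.

Two scores quantify how well the flux predictions agree with independent
data.  The consistency coefficient eta is the fraction of genes (or enzymes)
predicted active in silico — restricted to a fixed scope of reference
pathways — that were also detected by transcriptome/proteome experiments.
The overlapping coefficient Omega compares the metabolite sets of two active
subnetworks (shared over union), quantifying how robust the optimal network
fingerprint is across environmental conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network_model import MetabolicModel
from .optimization import DEFAULT_EPSILON, FluxDistribution

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayScope",
    "ConsistencyReport",
    "predicted_active_sets",
    "consistency_coefficient",
    "overlap_coefficient",
    "overlap_matrix",
    "read_detection_set",
    "pathway_scope_from_model",
]


@dataclass
class PathwayScope:
    """Reference pathway membership for genes and enzymes.

    ``genes[pathway]`` / ``enzymes[pathway]`` are the full reference sets
    (e.g. all genes a pathway database assigns to that pathway); the scope of
    the consistency score is their union.
    """

    genes: dict[str, set[str]] = field(default_factory=dict)
    enzymes: dict[str, set[str]] = field(default_factory=dict)

    def sets(self, kind: str) -> dict[str, set[str]]:
        if kind not in ("gene", "enzyme"):
            raise ValueError(f"kind must be 'gene' or 'enzyme', got {kind!r}")
        return self.genes if kind == "gene" else self.enzymes

    def union(self, kind: str) -> set[str]:
        out: set[str] = set()
        for members in self.sets(kind).values():
            out |= members
        return out

    @classmethod
    def from_tsv(cls, path) -> "PathwayScope":
        """Columns: pathway, member_id, type in {gene, enzyme}."""
        table = pd.read_csv(path, sep="\t")
        scope = cls()
        for _, row in table.iterrows():
            target = scope.sets(str(row["type"]))
            target.setdefault(str(row["pathway"]), set()).add(str(row["member_id"]))
        return scope

    def to_tsv(self, path) -> None:
        rows = []
        for kind in ("gene", "enzyme"):
            for pathway, members in sorted(self.sets(kind).items()):
                rows.extend({"pathway": pathway, "member_id": m, "type": kind}
                            for m in sorted(members))
        pd.DataFrame(rows, columns=["pathway", "member_id", "type"]).to_csv(
            path, sep="\t", index=False)


def pathway_scope_from_model(model: MetabolicModel) -> PathwayScope:
    """Scope built from the model's own pathway annotations (every annotated
    gene/enzyme of every pathway label)."""
    scope = PathwayScope()
    for rxn in model.reactions:
        for pathway in rxn.pathways:
            scope.genes.setdefault(pathway, set()).update(rxn.genes)
            scope.enzymes.setdefault(pathway, set()).update(rxn.enzymes)
    return scope


def predicted_active_sets(model: MetabolicModel, fluxes,
                          epsilon: float = DEFAULT_EPSILON
                          ) -> tuple[set[str], set[str]]:
    """Genes and enzymes annotated to reactions carrying flux above epsilon."""
    if isinstance(fluxes, FluxDistribution):
        fluxes = fluxes.model_fluxes(model)
    fluxes = np.asarray(fluxes, dtype=float)
    if fluxes.shape != (len(model.reactions),):
        raise ValueError("flux vector length does not match model reactions")
    genes: set[str] = set()
    enzymes: set[str] = set()
    for rxn, v in zip(model.reactions, fluxes):
        if abs(v) > epsilon:
            genes |= rxn.genes
            enzymes |= rxn.enzymes
    return genes, enzymes


@dataclass
class ConsistencyReport:
    """Pooled consistency coefficient plus the per-pathway breakdown.

    ``eta`` is None (flagged undefined) when nothing predicted falls inside
    the scope — an empty denominator is not a zero score.
    """

    kind: str
    eta: float | None
    n_detected_predicted: int
    n_predicted: int
    per_pathway: pd.DataFrame

    def to_tsv(self, path) -> None:
        header = pd.DataFrame([{
            "pathway": "__pooled__",
            "cbm_not_ht": self.n_predicted - self.n_detected_predicted,
            "cbm_and_ht": self.n_detected_predicted,
            "ht_not_cbm": int(self.per_pathway["ht_not_cbm"].sum())
                          if len(self.per_pathway) else 0,
            "eta": np.nan if self.eta is None else self.eta,
        }])
        pd.concat([header, self.per_pathway], ignore_index=True).to_csv(
            path, sep="\t", index=False)


def consistency_coefficient(predicted: set[str], detected: set[str],
                            scope: PathwayScope, kind: str = "gene"
                            ) -> ConsistencyReport:
    """Fraction of scope-restricted predictions confirmed by detection.

    Predictions are first restricted to the union of the scope's pathway
    sets; eta = |predicted & detected| / |predicted| on that restriction
    (pooled over pathways, which reproduces the detected/total coverage
    ratio).  The per-pathway breakdown partitions each pathway's relevant
    members into predicted-only, predicted-and-detected, detected-only.
    """
    scope_union = scope.union(kind)
    in_scope = set(predicted) & scope_union
    rows = []
    for pathway, members in sorted(scope.sets(kind).items()):
        pred_p = in_scope & members
        det_p = set(detected) & members
        both = pred_p & det_p
        rows.append({
            "pathway": pathway,
            "cbm_not_ht": len(pred_p - det_p),
            "cbm_and_ht": len(both),
            "ht_not_cbm": len(det_p - pred_p),
            "eta": len(both) / len(pred_p) if pred_p else np.nan,
        })
    n_pred = len(in_scope)
    n_both = len(in_scope & set(detected))
    eta = n_both / n_pred if n_pred else None
    if eta is None:
        logger.warning("consistency coefficient undefined: no predicted %ss "
                       "inside the pathway scope", kind)
    return ConsistencyReport(kind=kind, eta=eta,
                             n_detected_predicted=n_both, n_predicted=n_pred,
                             per_pathway=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Subnetwork overlap
# ---------------------------------------------------------------------------

def overlap_coefficient(nodes_i: set[str], nodes_j: set[str]) -> float:
    """Shared-over-union metabolite overlap: common / (only_i + only_j + common).

    Ranges from 1 (identical sets) to 0 (disjoint).  Two empty sets count as
    fully overlapping (1); empty vs non-empty is 0.
    """
    nodes_i, nodes_j = set(nodes_i), set(nodes_j)
    if not nodes_i and not nodes_j:
        return 1.0
    union = nodes_i | nodes_j
    return len(nodes_i & nodes_j) / len(union)


def overlap_matrix(subnetworks, labels: list[str] | None = None
                   ) -> tuple[list[str], np.ndarray]:
    """Pairwise overlapping coefficients between active-subnetwork node sets.

    ``subnetworks`` is an ordered list of graphs (or plain node sets).
    """
    if len(subnetworks) == 0:
        raise ValueError("need at least one subnetwork")
    node_sets = [set(g.nodes) if isinstance(g, nx.Graph) else set(g)
                 for g in subnetworks]
    if labels is None:
        labels = [str(i) for i in range(len(node_sets))]
    n = len(node_sets)
    omega = np.ones((n, n))
    for i in range(n):
        for j in range(i, n):
            omega[i, j] = omega[j, i] = overlap_coefficient(node_sets[i], node_sets[j])
    return labels, omega


def read_detection_set(path) -> set[str]:
    """One identifier per line (transcriptome / proteome detection sets)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_detection_set(members: set[str], path) -> None:
    with open(path, "w") as fh:
        for member in sorted(members):
            fh.write(member + "\n")
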