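"""Structural module detection on the metabolite graph.

Closeness between two metabolites is measured as the inverse square of their
shortest path length, 1/d^2, which amplifies near neighbours and damps remote
pairs.  Each metabolite is then described by its row of the association
matrix, rows are compared with Kendall's tau (tie-corrected tau-b, since path
lengths are heavily tied), and the resulting 1 - tau distances are clustered
with average-linkage agglomeration.  Cutting the tree yields the structural
modules, which are finally characterised by functional class composition and
by the coherence of their members' metabolome response.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import kendalltau

from .metabolome_of import DifferentialResult

logger = logging.getLogger(__name__)

__all__ = [
    "FUNCTIONAL_CLASSES",
    "ModulePartition",
    "shortest_path_matrix",
    "association_matrix",
    "tau_distance_matrix",
    "detect_modules",
    "module_composition",
    "module_coherence",
    "read_annotation",
]

FUNCTIONAL_CLASSES = ("nucleic_acid", "peptide", "lipid")
UNCLASSIFIED = "unclassified"


def shortest_path_matrix(graph: nx.Graph,
                         nodes: list[str] | None = None
                         ) -> tuple[list[str], np.ndarray]:
    """All-pairs unweighted shortest path lengths.

    Returns the node order used and a symmetric matrix with zeros on the
    diagonal and ``np.inf`` for disconnected pairs.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    nodes = list(graph.nodes) if nodes is None else list(nodes)
    index = {n: i for i, n in enumerate(nodes)}
    D = np.full((len(nodes), len(nodes)), np.inf)
    np.fill_diagonal(D, 0.0)
    for source, lengths in nx.all_pairs_shortest_path_length(graph):
        i = index[source]
        for target, d in lengths.items():
            D[i, index[target]] = float(d)
    return nodes, D


def association_matrix(D: np.ndarray) -> np.ndarray:
    """A_ij = 1/d_ij^2 off-diagonal; 0 for disconnected pairs; diagonal 1.

    The diagonal value is a convention (1/0^2 is undefined); it is excluded
    pairwise when rows are compared, so it never influences the clustering.
    """
    with np.errstate(divide="ignore"):
        A = 1.0 / np.square(D)
    A[np.isinf(D)] = 0.0
    np.fill_diagonal(A, 1.0)
    return A


def tau_distance_matrix(A: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Kendall tau-b between rows of the association matrix.

    For rows i and j the entries at positions i and j (the self-closeness
    conventions) are dropped from both rows before computing tau.  Identical
    rows are distance 0 by definition; an otherwise undefined tau (e.g. a
    fully tied row, where rank correlation carries no signal) is taken as 0,
    i.e. distance 1.
    """
    n = A.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.ones(n, dtype=bool)
            mask[[i, j]] = False
            x, y = A[i, mask], A[j, mask]
            if np.array_equal(x, y):
                continue  # identical profiles: distance stays 0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tau = kendalltau(x, y).statistic
            if np.isnan(tau):
                tau = 0.0
            dist[i, j] = dist[j, i] = 1.0 - tau
    return dist


@dataclass
class ModulePartition:
    """Module labels (contiguous 1..k) plus the linkage tree for audit."""

    assignment: dict[str, int]
    k: int
    linkage_matrix: np.ndarray

    def members(self, label: int) -> list[str]:
        return [n for n, lab in self.assignment.items() if lab == label]

    def labels(self, nodes: list[str]) -> list[int]:
        return [self.assignment[n] for n in nodes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.assignment.items()),
                            columns=["metabolite_id", "module"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def detect_modules(A: np.ndarray, nodes: list[str],
                   k: int | None = 9,
                   cut: str | None = None) -> ModulePartition:
    """Average-linkage clustering of association-matrix rows.

    ``k`` cuts the tree into a fixed number of modules (default 9, the count
    reported for the full reconstruction); ``cut="max_gap"`` instead places
    the cut at the largest gap between consecutive merge heights.  Labels are
    renumbered 1..k by first appearance in the given node order, so the
    output is equivariant under node relabeling.
    """
    n = A.shape[0]
    if A.shape != (n, n) or len(nodes) != n:
        raise ValueError("association matrix and node list sizes disagree")
    if cut is None and (k is None or not (1 <= k <= n)):
        raise ValueError(f"k must be between 1 and {n}")
    if n == 1:
        return ModulePartition({nodes[0]: 1}, 1, np.empty((0, 4)))
    dist = tau_distance_matrix(A)
    condensed = dist[np.triu_indices(n, k=1)]
    Z = linkage(condensed, method="average")
    if cut == "max_gap":
        heights = Z[:, 2]
        if len(heights) == 1:
            raw = fcluster(Z, t=1, criterion="maxclust")
        else:
            gaps = np.diff(heights)
            split = int(np.argmax(gaps))
            threshold = (heights[split] + heights[split + 1]) / 2.0
            raw = fcluster(Z, t=threshold, criterion="distance")
    elif cut is None:
        raw = fcluster(Z, t=k, criterion="maxclust")
    else:
        raise ValueError(f"unknown cut rule {cut!r}")
    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for node, lab in zip(nodes, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        assignment[node] = relabel[lab]
    part = ModulePartition(assignment, k=len(relabel), linkage_matrix=Z)
    logger.info("detected %d modules over %d metabolites", part.k, n)
    return part


def read_annotation(path) -> dict[str, str]:
    """Annotation TSV (metabolite_id, class) -> total function over any id."""
    table = pd.read_csv(path, sep="\t")
    return dict(zip(table["metabolite_id"].astype(str), table["class"].astype(str)))


def module_composition(partition: ModulePartition,
                       annotation: dict[str, str]) -> pd.DataFrame:
    """Per-module class fractions among classified members.

    Unknown ids count as unclassified.  Fractions are over classified members
    only; raw counts (including the unclassified tally) are reported
    alongside.
    """
    rows = []
    for label in range(1, partition.k + 1):
        members = partition.members(label)
        counts = {cls: 0 for cls in FUNCTIONAL_CLASSES}
        unclassified = 0
        for met in members:
            cls = annotation.get(met, UNCLASSIFIED)
            if cls in counts:
                counts[cls] += 1
            else:
                unclassified += 1
        n_classified = sum(counts.values())
        row = {"module": label, "n_members": len(members),
               "n_classified": n_classified, "n_unclassified": unclassified}
        for cls, c in counts.items():
            row[f"n_{cls}"] = c
            row[f"frac_{cls}"] = c / n_classified if n_classified else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def module_coherence(partition: ModulePartition,
                     results: list[DifferentialResult],
                     name_map: dict[str, str]) -> pd.DataFrame:
    """Do the metabolome-detected members of a module move together?

    Members are matched to differential results through the metabolome-name
    to model-id map; a member counts as "up" when its log2 ratio is positive.
    Modules with no matched member get an undefined (NaN) up-fraction.
    """
    by_id: dict[str, DifferentialResult] = {}
    for res in results:
        if res.status != "both":
            continue
        model_id = name_map.get(res.metabolite)
        if model_id is not None:
            by_id[model_id] = res
    rows = []
    for label in range(1, partition.k + 1):
        members = partition.members(label)
        matched = [(m, by_id[m]) for m in members if m in by_id]
        n_up = sum(1 for _, r in matched if r.log_ratio > 0)
        rows.append({
            "module": label,
            "n_members": len(members),
            "n_detected": len(matched),
            "n_up": n_up,
            "fraction_up": n_up / len(matched) if matched else np.nan,
            "directions": ";".join(f"{m}:{'up' if r.log_ratio > 0 else 'down'}"
                                   for m, r in matched),
        })
    return pd.DataFrame(rows)
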