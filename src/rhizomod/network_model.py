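"""Metabolic reconstruction parsing, stoichiometry and metabolite-graph projection.

A reconstruction is a list of reactions with signed stoichiometries over
compartment-tagged metabolite identifiers (``mal-L[c]``, ``nh4[e]``).  Two
derived views matter downstream: the stoichiometric matrix S (metabolites x
reactions) consumed by flux balance analysis, and an undirected metabolite
graph obtained by linking every reactant of a reaction to every product,
skipping currency species (cofactors, water, protons...) that would otherwise
short-circuit path lengths.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CURRENCY_METABOLITES",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ReactionParseError",
    "ModelValidationError",
    "parse_reaction_equation",
    "read_model",
    "write_model",
    "stoichiometric_matrix",
    "project_metabolite_graph",
    "active_subnetwork",
    "write_graphml",
    "write_edge_list",
]

#: Ubiquitous currency species excluded from graph projections by default.
#: These are cofactor/small-molecule pools whose hub-like connectivity would
#: create spurious two-step shortcuts between unrelated pathways.
CURRENCY_METABOLITES: frozenset[str] = frozenset({
    "pi[e]", "ala-L[e]", "accoa[e]", "glu-L[e]", "pi[c]", "fdp[c]",
    "nh4[e]", "nh3[c]", "nh3[e]", "h[e]", "ppi[c]", "o2[c]", "o2[e]",
    "nadph[c]", "nadp[c]", "nadh[c]", "nad[c]", "n2[c]", "n2[e]",
    "h2o2[c]", "h2o[c]", "h2o[e]", "h[c]", "fdred[c]", "fdox[c]",
    "fadh2[c]", "co2[c]", "co2[e]", "nh4[c]", "fad[c]",
})

_COMPARTMENT_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[a-zA-Z])\]$")

#: Default flux bounds (model flux units) when a table row leaves them blank.
DEFAULT_BOUNDS_REVERSIBLE = (-1000.0, 1000.0)
DEFAULT_BOUNDS_IRREVERSIBLE = (0.0, 1000.0)


class ReactionParseError(ValueError):
    """Raised when a reaction equation string cannot be parsed."""


class ModelValidationError(ValueError):
    """Raised with the full list of validation offenders, not just the first."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("model validation failed:\n  " + "\n  ".join(self.problems))


@dataclass(frozen=True)
class Metabolite:
    """A compartment-tagged species; ``is_currency`` is a pure function of id."""

    id: str
    name: str = ""
    compartment: str = "c"
    is_currency: bool = False

    @classmethod
    def from_id(cls, met_id: str, name: str = "",
                currency: frozenset[str] | set[str] = CURRENCY_METABOLITES) -> "Metabolite":
        m = _COMPARTMENT_RE.match(met_id)
        if m is None:
            raise ModelValidationError(
                [f"metabolite id {met_id!r} lacks a compartment suffix like [c]"])
        comp = m.group("comp")
        if comp not in ("c", "e"):
            raise ModelValidationError(
                [f"metabolite id {met_id!r}: compartment [{comp}] is not one of [c], [e]"])
        return cls(id=met_id, name=name or m.group("base"),
                   compartment=comp, is_currency=met_id in currency)


@dataclass
class Reaction:
    """One biochemical conversion.

    ``stoichiometry`` maps metabolite id to the signed coefficient S_ij
    (negative = consumed, positive = produced).  Reversibility is carried in
    the bounds, not in S.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""
    genes: frozenset[str] = frozenset()
    enzymes: frozenset[str] = frozenset()
    pathways: frozenset[str] = frozenset()

    @property
    def reactants(self) -> list[str]:
        return sorted(m for m, c in self.stoichiometry.items() if c < 0)

    @property
    def products(self) -> list[str]:
        return sorted(m for m, c in self.stoichiometry.items() if c > 0)

    def validate(self) -> list[str]:
        problems = []
        if not self.stoichiometry:
            problems.append(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            problems.append(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}")
        if not self.reversible and self.lower_bound < 0:
            problems.append(
                f"reaction {self.id!r}: irreversible but lower bound {self.lower_bound} < 0")
        return problems


def parse_reaction_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 h[c] + x[c] -> y[c]"`` into a signed stoichiometry map.

    Exactly one arrow token must be present: ``->`` (irreversible) or ``<=>``
    (reversible).  Terms are ``coeff id`` with an implicit coefficient of 1.
    Species repeated on one side are summed; a species on both sides is
    net-summed (and dropped if the net coefficient is zero).  Either side may
    be empty, which is how exchange and sink reactions are written.
    """
    n_rev = text.count("<=>")
    n_irr = text.count("->")
    if n_rev + n_irr != 1:
        raise ReactionParseError(
            f"equation must contain exactly one '->' or '<=>' arrow: {text!r}")
    reversible = n_rev == 1
    left, right = text.split("<=>" if reversible else "->")

    stoich: dict[str, float] = {}

    def _add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in re.split(r"\s+\+\s+", side):
            tokens = term.split()
            if len(tokens) == 1:
                coeff, met = 1.0, tokens[0]
            elif len(tokens) == 2:
                try:
                    coeff = float(tokens[0])
                except ValueError:
                    raise ReactionParseError(
                        f"non-numeric coefficient {tokens[0]!r} in term {term!r} "
                        f"of equation {text!r}") from None
                met = tokens[1]
            else:
                raise ReactionParseError(
                    f"cannot parse term {term!r} in equation {text!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    _add_side(left, -1.0)
    _add_side(right, +1.0)
    return {m: c for m, c in stoich.items() if c != 0.0}, reversible


@dataclass
class MetabolicModel:
    """Ordered metabolites + reactions with a currency exclusion list."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    currency_list: frozenset[str] = CURRENCY_METABOLITES

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite_index(self, met_id: str) -> int:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    @classmethod
    def from_reactions(cls, reactions: list[Reaction],
                       currency: frozenset[str] = CURRENCY_METABOLITES,
                       metabolite_names: dict[str, str] | None = None) -> "MetabolicModel":
        """Build a model whose metabolite list is derived from the reactions
        (first-appearance order), then validate it."""
        seen: dict[str, Metabolite] = {}
        problems: list[str] = []
        for rxn in reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in seen:
                    try:
                        name = (metabolite_names or {}).get(met_id, "")
                        seen[met_id] = Metabolite.from_id(met_id, name=name, currency=currency)
                    except ModelValidationError as exc:
                        problems.extend(exc.problems)
        if problems:
            raise ModelValidationError(problems)
        model = cls(metabolites=list(seen.values()), reactions=list(reactions),
                    currency_list=currency)
        model.validate()
        return model

    def validate(self) -> None:
        problems: list[str] = []
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
            problems.append(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            problems.append(f"duplicate reaction ids: {dupes}")
        known = set(met_ids)
        for rxn in self.reactions:
            problems.extend(rxn.validate())
            for met_id in rxn.stoichiometry:
                if met_id not in known:
                    problems.append(
                        f"reaction {rxn.id!r}: unresolvable metabolite id {met_id!r}")
        if problems:
            raise ModelValidationError(problems)

    def copy(self) -> "MetabolicModel":
        from copy import deepcopy
        return MetabolicModel(metabolites=list(self.metabolites),
                              reactions=deepcopy(self.reactions),
                              currency_list=self.currency_list)


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense S of shape ``|metabolites| x |reactions|`` in model order."""
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            S[model.metabolite_index(met_id), j] = coeff
    return S


# ---------------------------------------------------------------------------
# Canonical reconstruction table IO
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["reaction_id", "name", "equation", "lower_bound",
                  "upper_bound", "genes", "enzymes", "pathways"]


def _split_field(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    text = str(value).strip()
    if not text:
        return frozenset()
    return frozenset(t.strip() for t in text.split(";") if t.strip())


def read_model(path, format: str = "canonical-table",
               currency: frozenset[str] = CURRENCY_METABOLITES) -> MetabolicModel:
    """Read a reconstruction from the canonical TSV/CSV table or from SBML.

    Canonical-table columns: reaction_id, name, equation, lower_bound,
    upper_bound, genes, enzymes, pathways (the last three semicolon-separated;
    bounds blank = defaults).  SBML import goes through ``cobra``.
    """
    if format == "sbml":
        return _read_sbml(path, currency)
    if format != "canonical-table":
        raise ValueError(f"unknown model format {format!r}")
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, dtype={"reaction_id": str})
    missing = [c for c in ("reaction_id", "equation") if c not in table.columns]
    if missing:
        raise ModelValidationError([f"canonical table missing column {c!r}" for c in missing])
    reactions = []
    problems: list[str] = []
    for _, row in table.iterrows():
        try:
            stoich, reversible = parse_reaction_equation(str(row["equation"]))
        except ReactionParseError as exc:
            problems.append(str(exc))
            continue
        lb_default, ub_default = (DEFAULT_BOUNDS_REVERSIBLE if reversible
                                  else DEFAULT_BOUNDS_IRREVERSIBLE)
        lb = row.get("lower_bound")
        ub = row.get("upper_bound")
        lb = lb_default if lb is None or pd.isna(lb) else float(lb)
        ub = ub_default if ub is None or pd.isna(ub) else float(ub)
        reactions.append(Reaction(
            id=str(row["reaction_id"]),
            name="" if pd.isna(row.get("name", "")) else str(row.get("name", "")),
            stoichiometry=stoich, reversible=reversible,
            lower_bound=lb, upper_bound=ub,
            genes=_split_field(row.get("genes")),
            enzymes=_split_field(row.get("enzymes")),
            pathways=_split_field(row.get("pathways")),
        ))
    if problems:
        raise ModelValidationError(problems)
    model = MetabolicModel.from_reactions(reactions, currency=currency)
    logger.info("read %d reactions / %d metabolites from %s",
                len(model.reactions), len(model.metabolites), path)
    return model


def _read_sbml(path, currency: frozenset[str]) -> MetabolicModel:
    from cobra.io import read_sbml_model

    cb = read_sbml_model(str(path))
    reactions = []
    for rxn in cb.reactions:
        stoich = {f"{m.id if m.id.endswith(']') else m.id + '[' + (m.compartment or 'c') + ']'}": c
                  for m, c in rxn.metabolites.items()}
        reversible = rxn.lower_bound < 0
        reactions.append(Reaction(
            id=rxn.id, name=rxn.name or "", stoichiometry=stoich,
            reversible=reversible,
            lower_bound=float(rxn.lower_bound), upper_bound=float(rxn.upper_bound),
            genes=frozenset(g.id for g in rxn.genes),
            enzymes=frozenset(),
            pathways=frozenset([rxn.subsystem]) if rxn.subsystem else frozenset(),
        ))
    return MetabolicModel.from_reactions(reactions, currency=currency)


def format_equation(rxn: Reaction) -> str:
    """Render a stoichiometry back into the canonical equation dialect."""
    def _side(ids: list[str], sign: float) -> str:
        terms = []
        for met in ids:
            coeff = abs(rxn.stoichiometry[met])
            if coeff == 1.0:
                terms.append(met)
            else:
                c = int(coeff) if float(coeff).is_integer() else coeff
                terms.append(f"{c} {met}")
        return " + ".join(terms)

    arrow = "<=>" if rxn.reversible else "->"
    return f"{_side(rxn.reactants, -1)} {arrow} {_side(rxn.products, +1)}".strip()


def write_model(model: MetabolicModel, path) -> None:
    """Write the canonical reconstruction table (round-trips with read_model)."""
    rows = []
    for rxn in model.reactions:
        rows.append({
            "reaction_id": rxn.id,
            "name": rxn.name,
            "equation": format_equation(rxn),
            "lower_bound": rxn.lower_bound,
            "upper_bound": rxn.upper_bound,
            "genes": ";".join(sorted(rxn.genes)),
            "enzymes": ";".join(sorted(rxn.enzymes)),
            "pathways": ";".join(sorted(rxn.pathways)),
        })
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Metabolite-graph projection
# ---------------------------------------------------------------------------

def project_metabolite_graph(model: MetabolicModel,
                             exclusion: set[str] | None = None,
                             reactions: list[Reaction] | None = None,
                             keep_isolated: bool = True) -> nx.Graph:
    """Undirected reactant-to-product projection of the reconstruction.

    For every reaction, each (reactant, product) pair with both members
    outside the exclusion list becomes an edge; reactant-reactant and
    product-product pairs do not.  The graph is simple: duplicate edges from
    different reactions collapse, with the contributing reaction ids retained
    in the ``reactions`` edge attribute.
    """
    if exclusion is None:
        exclusion = set(model.currency_list)
    graph = nx.Graph()
    if keep_isolated:
        graph.add_nodes_from(m.id for m in model.metabolites if m.id not in exclusion)
    for rxn in (model.reactions if reactions is None else reactions):
        for r in rxn.reactants:
            if r in exclusion:
                continue
            for p in rxn.products:
                if p in exclusion or p == r:
                    continue
                if graph.has_edge(r, p):
                    graph[r][p]["reactions"].append(rxn.id)
                else:
                    graph.add_edge(r, p, reactions=[rxn.id])
    return graph


def active_subnetwork(model: MetabolicModel, fluxes, epsilon: float = 1e-6,
                      exclusion: set[str] | None = None) -> nx.Graph:
    """Projection restricted to reactions carrying flux above ``epsilon``.

    ``fluxes`` is indexed like ``model.reactions``; the node set is the set of
    endpoints of surviving edges (no isolated nodes).
    """
    fluxes = np.asarray(fluxes, dtype=float)
    if fluxes.shape != (len(model.reactions),):
        raise ValueError(
            f"flux vector length {fluxes.shape} does not match "
            f"{len(model.reactions)} reactions")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    active = [rxn for rxn, v in zip(model.reactions, fluxes) if abs(v) > epsilon]
    return project_metabolite_graph(model, exclusion=exclusion,
                                    reactions=active, keep_isolated=False)


def write_graphml(graph: nx.Graph, path) -> None:
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for u, v, data in graph.edges(data=True):
        g.add_edge(u, v, reactions=";".join(data.get("reactions", [])))
    nx.write_graphml(g, path)


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")
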