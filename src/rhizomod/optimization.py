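"""Flux balance analysis: objective drains, LP solution, phase planes, scans.

The nitrogen-fixation phenotype is encoded as an objective function Z = sum_i
c_i * v_i over drain fluxes of key metabolites (amino acids, TCA
intermediates, storage polymers, exported ammonium...).  Maximising Z subject
to the steady-state constraint S.v = 0 and per-reaction bounds alpha_j <= v_j
<= beta_j is a linear programme, solved here with HiGHS via scipy.

Because LP optima are frequently degenerate, the active subnetwork (reactions
with |v| above a threshold) is not unique.  By default we therefore fix the
optimal Z and minimise the total absolute flux (a parsimonious second stage,
linearised with auxiliary variables), which makes the reported subnetwork a
reproducible fingerprint of the condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from .network_model import (MetabolicModel, Reaction, active_subnetwork,
                            stoichiometric_matrix)

logger = logging.getLogger(__name__)

__all__ = [
    "BASE_NITROGEN_FIXATION_OF",
    "NITROGEN_FIXATION_OF",
    "ObjectiveFunction",
    "FluxDistribution",
    "PhasePlane",
    "ScanPoint",
    "attach_objective_sinks",
    "solve_fba",
    "phenotype_phase_plane",
    "diagonal_scan",
]

#: Drain threshold below which a flux counts as inactive (model flux units).
DEFAULT_EPSILON = 1e-6

_SINK_PREFIX = "SINK_"

#: Literature-derived core of the nitrogen-fixation objective: storage and
#: amino-acid species plus metabolites exchanged with the host plant ([e]).
_BASE_COMPONENTS = ("glycogen[c]", "hist[c]", "lys[c]", "phb[c]", "val[c]",
                    "ala[e]", "asp[e]", "nh4[e]")
#: Metabolome-derived additions (TCA intermediates, amino acids, CMP, 3PG).
_METABOLOME_COMPONENTS = ("mal-L[c]", "trp-L[c]", "arg-L[c]", "cit[c]",
                          "cmp[c]", "fum[c]", "3pg[c]", "akg[c]")


class ObjectiveError(ValueError):
    """Objective component cannot be attached or solved."""


@dataclass
class ObjectiveFunction:
    """Weighted set of drained metabolites; all default weights are 1."""

    components: dict[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        bad = {m: w for m, w in self.components.items() if w < 0}
        if bad:
            raise ObjectiveError(f"negative objective weights: {bad}")

    def with_component(self, met_id: str, weight: float = 1.0,
                       label: str | None = None) -> "ObjectiveFunction":
        comps = dict(self.components)
        comps[met_id] = weight
        return ObjectiveFunction(comps, label=self.label if label is None else label)

    def __len__(self) -> int:
        return len(self.components)


def base_nitrogen_fixation_of() -> ObjectiveFunction:
    """The pre-metabolome objective (8 components, unit weights)."""
    return ObjectiveFunction({m: 1.0 for m in _BASE_COMPONENTS}, label="Z_fix_base")


def nitrogen_fixation_of() -> ObjectiveFunction:
    """The full 16-component nitrogen-fixation objective, unit weights."""
    comps = {m: 1.0 for m in _BASE_COMPONENTS + _METABOLOME_COMPONENTS}
    return ObjectiveFunction(comps, label="Z_fix")


BASE_NITROGEN_FIXATION_OF = base_nitrogen_fixation_of()
NITROGEN_FIXATION_OF = nitrogen_fixation_of()


@dataclass
class FluxDistribution:
    """An LP solution: per-reaction fluxes over the sink-augmented model."""

    reaction_ids: list[str]
    fluxes: np.ndarray
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def flux(self, rxn_id: str) -> float:
        return float(self.fluxes[self.reaction_ids.index(rxn_id)])

    def model_fluxes(self, model: MetabolicModel) -> np.ndarray:
        """Fluxes restricted to (and ordered like) ``model.reactions``."""
        idx = {r: i for i, r in enumerate(self.reaction_ids)}
        return np.array([self.fluxes[idx[r]] for r in model.reaction_ids])

    def active_reaction_ids(self, epsilon: float = DEFAULT_EPSILON) -> list[str]:
        return [r for r, v in zip(self.reaction_ids, self.fluxes) if abs(v) > epsilon]


def attach_objective_sinks(model: MetabolicModel, of: ObjectiveFunction
                           ) -> tuple[MetabolicModel, dict[str, str]]:
    """Add one irreversible drain reaction per objective component.

    Returns the augmented model and a map component id -> sink reaction id.
    The original reactions are untouched; sinks have bounds (0, 1000).
    """
    unknown = [m for m in of.components if not model.has_metabolite(m)]
    if unknown:
        raise ObjectiveError(f"objective components not in model: {sorted(unknown)}")
    sinks: dict[str, str] = {}
    new_reactions = list(model.reactions)
    for met_id in of.components:
        sink_id = _SINK_PREFIX + met_id
        if model.has_reaction(sink_id):
            raise ObjectiveError(f"sink reaction id {sink_id!r} already present")
        new_reactions.append(Reaction(
            id=sink_id, name=f"objective drain of {met_id}",
            stoichiometry={met_id: -1.0}, reversible=False,
            lower_bound=0.0, upper_bound=1000.0))
        sinks[met_id] = sink_id
    augmented = MetabolicModel(metabolites=list(model.metabolites),
                               reactions=new_reactions,
                               currency_list=model.currency_list)
    return augmented, sinks


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded",
           4: "numerical difficulty"}


def solve_fba(model: MetabolicModel, of: ObjectiveFunction,
              parsimonious: bool = True,
              forced_drains: dict[str, float] | None = None) -> FluxDistribution:
    """Maximise the objective drains at steady state.

    ``forced_drains`` optionally sets a lower bound (model flux units) on the
    sink of a component, demanding that it actually be produced; used by the
    objective-refinement audit.  With ``parsimonious`` (default), a second LP
    fixes the optimal Z and minimises total absolute flux so that the active
    subnetwork is reproducible across solvers and runs.
    """
    if not of.components:
        raise ObjectiveError("objective function is empty")
    augmented, sinks = attach_objective_sinks(model, of)
    if forced_drains:
        unknown = [m for m in forced_drains if m not in sinks]
        if unknown:
            raise ObjectiveError(f"forced drains not in objective: {sorted(unknown)}")
        for met_id, lb in forced_drains.items():
            augmented.reaction(sinks[met_id]).lower_bound = float(lb)

    S = stoichiometric_matrix(augmented)
    n = len(augmented.reactions)
    bounds = [(r.lower_bound, r.upper_bound) for r in augmented.reactions]
    c = np.zeros(n)
    for met_id, weight in of.components.items():
        c[augmented.reaction_ids.index(sinks[met_id])] = weight

    res = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs")
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxDistribution(augmented.reaction_ids, np.full(n, np.nan),
                                np.nan, status)
    z_opt = float(-res.fun)
    v = res.x
    if parsimonious:
        v = _parsimonious_fluxes(S, bounds, c, z_opt, v)
    return FluxDistribution(augmented.reaction_ids, v, z_opt, "optimal")


def _parsimonious_fluxes(S: np.ndarray, bounds: list[tuple[float, float]],
                         c: np.ndarray, z_opt: float, fallback: np.ndarray
                         ) -> np.ndarray:
    """min sum_j t_j  s.t.  S v = 0,  t >= |v|,  c.v >= Z* (within tolerance)."""
    n = S.shape[1]
    # variables [v, t]
    obj = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([S, np.zeros_like(S)])
    eye = np.eye(n)
    # v - t <= 0 ; -v - t <= 0 ; -c.v <= -(Z* - tol)
    tol = 1e-9 * max(1.0, abs(z_opt))
    A_ub = np.vstack([np.hstack([eye, -eye]),
                      np.hstack([-eye, -eye]),
                      np.concatenate([-c, np.zeros(n)])[None, :]])
    b_ub = np.concatenate([np.zeros(2 * n), [-(z_opt - tol)]])
    t_hi = max(abs(lo) if np.isfinite(lo) else 1e6 for lo, _ in bounds)
    t_hi = max(t_hi, max(abs(hi) if np.isfinite(hi) else 1e6 for _, hi in bounds))
    var_bounds = list(bounds) + [(0.0, t_hi)] * n
    res = linprog(obj, A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
                  A_ub=A_ub, b_ub=b_ub, bounds=var_bounds, method="highs")
    if res.status != 0:  # fall back to the first-stage solution
        logger.warning("parsimonious stage failed (%s); using first-stage fluxes",
                       _STATUS.get(res.status, "failed"))
        return fallback
    return res.x[:n]


# ---------------------------------------------------------------------------
# Phenotype phase plane and diagonal scan
# ---------------------------------------------------------------------------

def _cap_uptake(model: MetabolicModel, exchange_id: str, cap: float) -> None:
    """Limit the uptake magnitude of an exchange reaction (in place).

    Exchanges are oriented so that uptake into the cytoplasm is the positive
    direction; the cap bounds the positive flux at ``cap``.
    """
    if not model.has_reaction(exchange_id):
        raise ObjectiveError(f"unknown exchange reaction {exchange_id!r}")
    rxn = model.reaction(exchange_id)
    rxn.upper_bound = float(cap)
    rxn.lower_bound = min(rxn.lower_bound, float(cap))


@dataclass
class PhasePlane:
    """Optimal objective values over a 2-D grid of uptake caps."""

    exchange1: str
    exchange2: str
    grid1: np.ndarray
    grid2: np.ndarray
    Z: np.ndarray  # shape (len(grid1), len(grid2)); NaN where infeasible

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.Z,
                            index=pd.Index(self.grid1, name=self.exchange1),
                            columns=pd.Index(self.grid2, name=self.exchange2))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def phenotype_phase_plane(model: MetabolicModel, of: ObjectiveFunction,
                          exchange1: str, exchange2: str,
                          grid1=None, grid2=None,
                          parsimonious: bool = False) -> PhasePlane:
    """Sweep two uptake caps and record the optimal objective at each cell.

    Default grids are the integer caps 0..20 in model flux units.  Only the
    objective value is needed per cell, so the parsimonious stage is skipped
    by default.
    """
    grid1 = np.arange(21.0) if grid1 is None else np.asarray(grid1, dtype=float)
    grid2 = np.arange(21.0) if grid2 is None else np.asarray(grid2, dtype=float)
    if grid1.size == 0 or grid2.size == 0 or (grid1 < 0).any() or (grid2 < 0).any():
        raise ValueError("grids must be non-empty with non-negative caps")
    for ex in (exchange1, exchange2):
        if not model.has_reaction(ex):
            raise ObjectiveError(f"unknown exchange reaction {ex!r}")
    Z = np.full((grid1.size, grid2.size), np.nan)
    for i, u1 in enumerate(grid1):
        for j, u2 in enumerate(grid2):
            capped = model.copy()
            _cap_uptake(capped, exchange1, u1)
            _cap_uptake(capped, exchange2, u2)
            sol = solve_fba(capped, of, parsimonious=parsimonious)
            if sol.status == "optimal":
                Z[i, j] = sol.objective_value
    return PhasePlane(exchange1, exchange2, grid1, grid2, Z)


@dataclass
class ScanPoint:
    """One physiological condition along the diagonal of the phase plane."""

    index: int
    cap: float
    solution: FluxDistribution
    subnetwork: nx.Graph


def diagonal_scan(model: MetabolicModel, of: ObjectiveFunction,
                  exchange1: str, exchange2: str,
                  n_points: int = 20, hi: float = 20.0, lo: float = 0.0,
                  epsilon: float = DEFAULT_EPSILON,
                  parsimonious: bool = True) -> list[ScanPoint]:
    """Reduce both carbon-source uptakes simultaneously from ``hi`` to ``lo``.

    ``n_points`` equally spaced caps, endpoints inclusive, are applied to both
    exchanges at once; each condition is solved and its active subnetwork
    extracted (currency metabolites excluded as usual).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if not (hi > lo >= 0):
        raise ValueError("need hi > lo >= 0")
    points = []
    for i, cap in enumerate(np.linspace(hi, lo, n_points)):
        capped = model.copy()
        _cap_uptake(capped, exchange1, cap)
        _cap_uptake(capped, exchange2, cap)
        sol = solve_fba(capped, of, parsimonious=parsimonious)
        if sol.status == "optimal":
            graph = active_subnetwork(capped, sol.model_fluxes(capped), epsilon=epsilon)
        else:
            graph = nx.Graph()
        points.append(ScanPoint(index=i, cap=float(cap), solution=sol,
                                subnetwork=graph))
        logger.info("scan point %d: cap=%.3f status=%s Z=%.4f nodes=%d",
                    i, cap, sol.status, sol.objective_value,
                    graph.number_of_nodes())
    return points
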