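"""Differential metabolomics and metabolome-driven objective refinement.

Relative CE-MS peak areas, measured in triplicate under two physiological
conditions (nitrogen-fixing bacteroids, "bac", vs free-living cells, "vl"),
drive two steps: (1) a one-sided Welch t-test on log2 peak areas identifies
metabolites significantly more abundant during nitrogen fixation (fold >= 2,
p < 0.01 by default); (2) each candidate is tried as an additional drain in
the flux-balance objective and kept only if the network can actually produce
it at steady state without collapsing the phenotype — the audited optimum
must stay above one third of the previous objective value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network_model import MetabolicModel
from .optimization import ObjectiveFunction, solve_fba

logger = logging.getLogger(__name__)

__all__ = [
    "MetabolomeRecord",
    "DifferentialResult",
    "RefinementAudit",
    "AuditEntry",
    "read_metabolome",
    "write_metabolome",
    "differential_analysis",
    "select_candidates",
    "refine_objective",
    "read_name_map",
]

REPLICATES = 3


class MetabolomeFormatError(ValueError):
    pass


@dataclass
class MetabolomeRecord:
    """Triplicate relative peak areas of one metabolite in two conditions.

    Areas are dimensionless (internal-standard normalised).  A condition
    counts as detected only when all three replicates are present; otherwise
    the metabolite is condition-exclusive (or absent).
    """

    metabolite: str
    ion_mode: str  # cation | anion
    bac: tuple[float, ...] = ()
    vl: tuple[float, ...] = ()

    @property
    def detected_bac(self) -> bool:
        return len(self.bac) == REPLICATES

    @property
    def detected_vl(self) -> bool:
        return len(self.vl) == REPLICATES

    @property
    def status(self) -> str:
        if self.detected_bac and self.detected_vl:
            return "both"
        if self.detected_bac:
            return "bac_only"
        if self.detected_vl:
            return "vl_only"
        return "undetected"


@dataclass
class DifferentialResult:
    """Per-metabolite log2 ratio (bac over vl) and one-sided p-value."""

    metabolite: str
    status: str
    log_ratio: float = math.nan  # defined only for status == "both"
    p_value: float = math.nan

    @property
    def fold(self) -> float:
        return 2.0 ** self.log_ratio


def _replicate_columns(prefix: str) -> list[str]:
    return [f"{prefix}_{i}" for i in range(1, REPLICATES + 1)]


def read_metabolome(path) -> list[MetabolomeRecord]:
    """Read the metabolome TSV (columns: metabolite, ion_mode, bac_1..3,
    vl_1..3; blank cells mean not detected)."""
    table = pd.read_csv(path, sep="\t")
    needed = ["metabolite", "ion_mode"] + _replicate_columns("bac") + _replicate_columns("vl")
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise MetabolomeFormatError(f"metabolome table missing columns: {missing}")
    records = []
    for _, row in table.iterrows():
        bac = tuple(float(row[c]) for c in _replicate_columns("bac") if pd.notna(row[c]))
        vl = tuple(float(row[c]) for c in _replicate_columns("vl") if pd.notna(row[c]))
        if 0 < len(bac) < REPLICATES or 0 < len(vl) < REPLICATES:
            logger.warning("metabolite %r has a partial replicate set; "
                           "treating the condition as not detected", row["metabolite"])
            bac = bac if len(bac) == REPLICATES else ()
            vl = vl if len(vl) == REPLICATES else ()
        records.append(MetabolomeRecord(metabolite=str(row["metabolite"]),
                                        ion_mode=str(row["ion_mode"]),
                                        bac=bac, vl=vl))
    if not records:
        logger.warning("metabolome table %s is empty", path)
    modes = pd.Series([r.ion_mode for r in records]).value_counts().to_dict()
    logger.info("read %d metabolome records (%s)", len(records),
                ", ".join(f"{k}: {v}" for k, v in sorted(modes.items())))
    return records


def write_metabolome(records: list[MetabolomeRecord], path) -> None:
    rows = []
    for rec in records:
        row = {"metabolite": rec.metabolite, "ion_mode": rec.ion_mode}
        for i, col in enumerate(_replicate_columns("bac")):
            row[col] = rec.bac[i] if rec.detected_bac else ""
        for i, col in enumerate(_replicate_columns("vl")):
            row[col] = rec.vl[i] if rec.detected_vl else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def differential_analysis(records: list[MetabolomeRecord]) -> list[DifferentialResult]:
    """Log2 ratio of replicate means plus a one-sided Welch t-test.

    The test is applied to log2-transformed replicates with the alternative
    "bac > vl" (enrichment during nitrogen fixation).  Condition-exclusive
    metabolites are flagged, not tested.  Degenerate zero-variance cases:
    identical groups give p = 1 (no evidence), separated constant groups give
    p = 0.
    """
    results = []
    for rec in records:
        if rec.status != "both":
            results.append(DifferentialResult(rec.metabolite, rec.status))
            continue
        if min(rec.bac) <= 0 or min(rec.vl) <= 0:
            raise MetabolomeFormatError(
                f"metabolite {rec.metabolite!r}: non-positive peak area in a "
                "detected condition")
        log_bac = np.log2(rec.bac)
        log_vl = np.log2(rec.vl)
        log_ratio = float(np.log2(np.mean(rec.bac) / np.mean(rec.vl)))
        if np.ptp(log_bac) == 0 and np.ptp(log_vl) == 0:
            p = 1.0 if log_bac[0] == log_vl[0] else (0.0 if log_bac[0] > log_vl[0] else 1.0)
        else:
            p = float(stats.ttest_ind(log_bac, log_vl, equal_var=False,
                                      alternative="greater").pvalue)
        results.append(DifferentialResult(rec.metabolite, "both",
                                          log_ratio=log_ratio, p_value=p))
    return results


def select_candidates(results: list[DifferentialResult],
                      min_fold: float = 2.0,
                      max_p: float = 0.01) -> list[DifferentialResult]:
    """Metabolites enriched in bacteroids: fold >= min_fold and p < max_p,
    ordered by decreasing log ratio (strongest signal first)."""
    if min_fold < 1.0:
        raise ValueError("min_fold must be >= 1")
    selected = [r for r in results
                if r.status == "both" and r.fold >= min_fold and r.p_value < max_p]
    return sorted(selected, key=lambda r: (-r.log_ratio, r.metabolite))


# ---------------------------------------------------------------------------
# Objective refinement
# ---------------------------------------------------------------------------

@dataclass
class AuditEntry:
    candidate: str
    model_id: str | None
    z_before: float
    z_after: float  # NaN when the audited LP was infeasible/unbounded
    accepted: bool
    reason: str


@dataclass
class RefinementAudit:
    """Ordered trail of every candidate trial during objective refinement."""

    entries: list[AuditEntry] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class RefinementError(ValueError):
    pass


def refine_objective(model: MetabolicModel,
                     base_of: ObjectiveFunction,
                     candidates: list[DifferentialResult] | list[str],
                     name_map: dict[str, str],
                     retention: float = 1.0 / 3.0,
                     min_drain: float = 1.0,
                     ) -> tuple[ObjectiveFunction, RefinementAudit]:
    """Grow the objective with metabolome candidates that the network sustains.

    Candidates are tried sequentially in the given order.  For each mapped
    candidate the objective is augmented with a unit-weight drain that must
    carry at least ``min_drain`` flux (the audit probe: the metabolite must
    actually be producible at steady state).  The candidate is kept iff that
    probe LP is feasible and bounded and its optimum Z_after stays at or
    above ``retention`` times the previous accepted objective's optimum.
    """
    base_sol = solve_fba(model, base_of, parsimonious=False)
    if base_sol.status != "optimal":
        raise RefinementError(
            f"base objective is not solvable on this model: {base_sol.status}")
    current = ObjectiveFunction(dict(base_of.components),
                                label=base_of.label or "refined")
    z_prev = base_sol.objective_value
    audit = RefinementAudit()
    for cand in candidates:
        name = cand.metabolite if isinstance(cand, DifferentialResult) else str(cand)
        model_id = name_map.get(name)
        if model_id is None or not model.has_metabolite(model_id):
            audit.entries.append(AuditEntry(name, model_id, z_prev, math.nan,
                                            False, "unmapped"))
            continue
        if model_id in current.components:
            audit.entries.append(AuditEntry(name, model_id, z_prev, z_prev,
                                            False, "already in objective"))
            continue
        trial = current.with_component(model_id, 1.0)
        probe = solve_fba(model, trial, parsimonious=False,
                          forced_drains={model_id: min_drain})
        if probe.status != "optimal":
            audit.entries.append(AuditEntry(
                name, model_id, z_prev, math.nan, False,
                f"no steady-state production ({probe.status})"))
            continue
        z_after = probe.objective_value
        if z_after < retention * z_prev:
            audit.entries.append(AuditEntry(
                name, model_id, z_prev, z_after, False,
                f"activity reduced below {retention:.3g} of previous objective"))
            continue
        current = trial
        accepted_sol = solve_fba(model, current, parsimonious=False)
        audit.entries.append(AuditEntry(name, model_id, z_prev, z_after, True,
                                        "accepted"))
        z_prev = accepted_sol.objective_value
    logger.info("objective refinement: %d candidates tried, %d accepted "
                "(final |OF| = %d)", len(audit.entries),
                sum(e.accepted for e in audit.entries), len(current))
    return current, audit


def read_name_map(path) -> dict[str, str]:
    """Two-column TSV mapping metabolome names to model metabolite ids."""
    table = pd.read_csv(path, sep="\t")
    cols = list(table.columns[:2])
    return dict(zip(table[cols[0]].astype(str), table[cols[1]].astype(str)))


def write_objective(of: ObjectiveFunction, path) -> None:
    pd.DataFrame(sorted(of.components.items()),
                 columns=["metabolite", "weight"]).to_csv(path, sep="\t", index=False)


def read_objective(path, label: str = "") -> ObjectiveFunction:
    table = pd.read_csv(path, sep="\t")
    return ObjectiveFunction(dict(zip(table["metabolite"], table["weight"].astype(float))),
                             label=label)
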