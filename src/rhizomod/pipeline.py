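"""End-to-end orchestration with a config file, seeds, and run manifests.

Stages (each writes its artifacts plus a JSON manifest under the output
directory):

  simulate     generate synthetic inputs (reconstruction, metabolome,
               annotations, name map, detection sets, pathway scope, truth)
  fba          solve the nitrogen-fixation LP on the configured model
  refine-of    differential metabolomics + objective refinement audit
  modules      structural module detection, composition, coherence
  phase-plane  2-D uptake sweep and the diagonal scan with active subnetworks
  assess       consistency coefficients and the subnetwork overlap matrix
  report       collate everything into one summary JSON
  all          run the stages above in order
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assessment, metabolome_of, network_model, optimization, synthetic, topology

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fba", "refine-of", "modules", "phase-plane",
          "assess", "report")


class PipelineDependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults are the study's settings."""

    outdir: str = "rhizomod_out"
    seed: int = 0
    # input paths; blank means "use the simulate stage's outputs"
    model_path: str = ""
    metabolome_path: str = ""
    annotation_path: str = ""
    name_map_path: str = ""
    detected_genes_path: str = ""
    detected_enzymes_path: str = ""
    pathway_scope_path: str = ""
    # thresholds
    min_fold: float = 2.0
    max_p: float = 0.01
    epsilon: float = 1e-6
    of_retention: float = 1.0 / 3.0
    min_drain: float = 1.0
    # module detection
    n_modules: int = 9
    module_cut: str = ""  # "" = fixed k; "max_gap" = largest-gap cut
    # phase plane / diagonal scan
    uptake_max: float = 20.0
    grid_points: int = 21
    diagonal_points: int = 20
    exchange1: str = ""
    exchange2: str = ""
    # synthetic generator overrides (simulate stage)
    synthetic: dict = field(default_factory=dict)

    def validate(self) -> None:
        problems = []
        if self.min_fold < 1:
            problems.append("min_fold must be >= 1")
        if not (0 < self.max_p <= 1):
            problems.append("max_p must be in (0, 1]")
        if self.epsilon <= 0:
            problems.append("epsilon must be > 0")
        if not (0 < self.of_retention <= 1):
            problems.append("of_retention must be in (0, 1]")
        if self.n_modules < 1:
            problems.append("n_modules must be >= 1")
        if self.diagonal_points < 2:
            problems.append("diagonal_points must be >= 2")
        if self.module_cut not in ("", "max_gap"):
            problems.append("module_cut must be '' or 'max_gap'")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _stage_dir(config: PipelineConfig, stage: str) -> Path:
    d = Path(config.outdir) / stage.replace("-", "_")
    d.mkdir(parents=True, exist_ok=True)
    return d


def _write_manifest(stage_dir: Path, stage: str, config: PipelineConfig,
                    inputs: dict, outputs: list[str]) -> None:
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in dataclasses.asdict(config).items()
                       if not k.endswith("_path") and k != "synthetic"},
        "inputs": inputs,
        "outputs": outputs,
    }
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _require(config: PipelineConfig, stage: str, needed_stage: str,
             filename: str) -> Path:
    path = Path(config.outdir) / needed_stage.replace("-", "_") / filename
    if not path.exists():
        raise PipelineDependencyError(
            f"stage {stage!r} needs {path} — run stage {needed_stage!r} first")
    return path


def _input_path(config: PipelineConfig, attr: str, stage: str,
                needed_stage: str, filename: str) -> Path:
    configured = getattr(config, attr)
    if configured:
        return Path(configured)
    return _require(config, stage, needed_stage, filename)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_simulate(config: PipelineConfig) -> None:
    out = _stage_dir(config, "simulate")
    spec_kwargs = dict(config.synthetic)
    spec_kwargs.setdefault("seed", config.seed)
    spec = synthetic.SyntheticSpec(**spec_kwargs)
    model, partition, base_of = synthetic.generate_toy_model(spec)
    network_model.write_model(model, out / "model.tsv")

    names = model.metabolite_ids
    records, met_truth = synthetic.generate_metabolome(names, spec)
    metabolome_of.write_metabolome(records, out / "metabolome.tsv")
    # metabolome names are the model ids themselves in the synthetic study
    pd.DataFrame({"metabolome_name": names, "model_id": names}).to_csv(
        out / "name_map.tsv", sep="\t", index=False)

    annotation = synthetic.planted_annotation(partition)
    pd.DataFrame(sorted(annotation.items()),
                 columns=["metabolite_id", "class"]).to_csv(
        out / "annotation.tsv", sep="\t", index=False)

    sol = optimization.solve_fba(model, base_of)
    active_genes, active_enzymes = assessment.predicted_active_sets(
        model, sol, epsilon=config.epsilon)
    genes, enzymes = synthetic.generate_ht_sets(model, active_genes,
                                                ht_tpr=spec.ht_tpr,
                                                fpr=spec.ht_fpr,
                                                seed=spec.seed + 3)
    assessment.write_detection_set(genes, out / "detected_genes.txt")
    assessment.write_detection_set(enzymes, out / "detected_enzymes.txt")
    assessment.pathway_scope_from_model(model).to_tsv(out / "pathway_scope.tsv")
    metabolome_of.write_objective(base_of, out / "base_objective.tsv")

    synthetic.truth_to_json(out / "truth.json",
                            spec=dataclasses.asdict(spec),
                            partition=partition,
                            objective=sorted(base_of.components),
                            active_genes=active_genes,
                            active_enzymes=active_enzymes,
                            **met_truth)
    _write_manifest(out, "simulate", config, inputs={},
                    outputs=[p.name for p in sorted(out.iterdir())])
    logger.info("simulate: %d reactions, %d metabolome records",
                len(model.reactions), len(records))


def _load_model(config: PipelineConfig, stage: str) -> network_model.MetabolicModel:
    path = _input_path(config, "model_path", stage, "simulate", "model.tsv")
    fmt = "sbml" if str(path).endswith((".xml", ".sbml")) else "canonical-table"
    return network_model.read_model(path, format=fmt)


def _load_objective(config: PipelineConfig, stage: str,
                    refined: bool = False) -> optimization.ObjectiveFunction:
    if refined:
        path = Path(config.outdir) / "refine_of" / "refined_objective.tsv"
        if path.exists():
            return metabolome_of.read_objective(path, label="Z_refined")
    base = Path(config.outdir) / "simulate" / "base_objective.tsv"
    if base.exists():
        return metabolome_of.read_objective(base, label="Z_base")
    return optimization.nitrogen_fixation_of()


def run_fba(config: PipelineConfig) -> None:
    out = _stage_dir(config, "fba")
    model = _load_model(config, "fba")
    of = _load_objective(config, "fba")
    sol = optimization.solve_fba(model, of)
    pd.DataFrame({"reaction_id": sol.reaction_ids, "flux": sol.fluxes}).to_csv(
        out / "fluxes.tsv", sep="\t", index=False)
    graph = network_model.active_subnetwork(model, sol.model_fluxes(model),
                                            epsilon=config.epsilon)
    network_model.write_graphml(graph, out / "active_subnetwork.graphml")
    network_model.write_edge_list(graph, out / "active_subnetwork.edges.tsv")
    with open(out / "solution.json", "w") as fh:
        json.dump({"status": sol.status, "objective_value": sol.objective_value,
                   "n_active": len(sol.active_reaction_ids(config.epsilon)),
                   "n_nodes": graph.number_of_nodes(),
                   "n_edges": graph.number_of_edges()}, fh, indent=2)
    _write_manifest(out, "fba", config,
                    inputs={"model": str(_input_path(config, "model_path", "fba",
                                                     "simulate", "model.tsv"))},
                    outputs=[p.name for p in sorted(out.iterdir())])
    logger.info("fba: status=%s Z=%.4f active nodes=%d", sol.status,
                sol.objective_value, graph.number_of_nodes())


def run_refine_of(config: PipelineConfig) -> None:
    out = _stage_dir(config, "refine_of")
    model = _load_model(config, "refine-of")
    met_path = _input_path(config, "metabolome_path", "refine-of",
                           "simulate", "metabolome.tsv")
    map_path = _input_path(config, "name_map_path", "refine-of",
                           "simulate", "name_map.tsv")
    records = metabolome_of.read_metabolome(met_path)
    results = metabolome_of.differential_analysis(records)
    pd.DataFrame([vars(r) for r in results]).to_csv(
        out / "differential.tsv", sep="\t", index=False)
    candidates = metabolome_of.select_candidates(results,
                                                 min_fold=config.min_fold,
                                                 max_p=config.max_p)
    base_of = _load_objective(config, "refine-of")
    refined, audit = metabolome_of.refine_objective(
        model, base_of, candidates, metabolome_of.read_name_map(map_path),
        retention=config.of_retention, min_drain=config.min_drain)
    audit.to_tsv(out / "audit.tsv")
    metabolome_of.write_objective(refined, out / "refined_objective.tsv")
    _write_manifest(out, "refine-of", config,
                    inputs={"metabolome": str(met_path), "name_map": str(map_path)},
                    outputs=[p.name for p in sorted(out.iterdir())])
    logger.info("refine-of: %d candidates, %d accepted, |OF| %d -> %d",
                len(candidates), sum(e.accepted for e in audit.entries),
                len(base_of), len(refined))


def run_modules(config: PipelineConfig) -> None:
    out = _stage_dir(config, "modules")
    model = _load_model(config, "modules")
    ann_path = _input_path(config, "annotation_path", "modules",
                           "simulate", "annotation.tsv")
    graph = network_model.project_metabolite_graph(model)
    nodes, D = topology.shortest_path_matrix(graph, nodes=[
        m.id for m in model.metabolites if m.id not in model.currency_list])
    A = topology.association_matrix(D)
    k = min(config.n_modules, len(nodes))
    partition = topology.detect_modules(
        A, nodes, k=None if config.module_cut else k,
        cut=config.module_cut or None)
    partition.to_tsv(out / "assignment.tsv")
    pd.DataFrame(partition.linkage_matrix,
                 columns=["left", "right", "height", "size"]).to_csv(
        out / "dendrogram_heights.tsv", sep="\t", index=False)
    annotation = topology.read_annotation(ann_path)
    topology.module_composition(partition, annotation).to_csv(
        out / "composition.tsv", sep="\t", index=False)
    diff_path = Path(config.outdir) / "refine_of" / "differential.tsv"
    if diff_path.exists():
        diff = pd.read_csv(diff_path, sep="\t")
        results = [metabolome_of.DifferentialResult(
            str(r.metabolite), str(r.status),
            log_ratio=float(r.log_ratio), p_value=float(r.p_value))
            for r in diff.itertuples()]
        map_path = _input_path(config, "name_map_path", "modules",
                               "simulate", "name_map.tsv")
        topology.module_coherence(
            partition, results, metabolome_of.read_name_map(map_path)).to_csv(
            out / "coherence.tsv", sep="\t", index=False)
    _write_manifest(out, "modules", config,
                    inputs={"annotation": str(ann_path)},
                    outputs=[p.name for p in sorted(out.iterdir())])
    logger.info("modules: %d modules over %d metabolites", partition.k, len(nodes))


def _exchange_ids(config: PipelineConfig, model) -> tuple[str, str]:
    if config.exchange1 and config.exchange2:
        return config.exchange1, config.exchange2
    exchanges = [r.id for r in model.reactions
                 if "exchange" in r.pathways and r.lower_bound != r.upper_bound]
    if len(exchanges) < 2:
        raise PipelineDependencyError(
            "phase-plane needs exchange1/exchange2 in the config (found "
            f"{len(exchanges)} candidate exchange reactions)")
    return exchanges[0], exchanges[1]


def run_phase_plane(config: PipelineConfig) -> None:
    out = _stage_dir(config, "phase_plane")
    model = _load_model(config, "phase-plane")
    of = _load_objective(config, "phase-plane", refined=True)
    ex1, ex2 = _exchange_ids(config, model)
    grid = np.linspace(0.0, config.uptake_max, config.grid_points)
    plane = optimization.phenotype_phase_plane(model, of, ex1, ex2,
                                               grid1=grid, grid2=grid)
    plane.to_tsv(out / "phase_plane.tsv")
    points = optimization.diagonal_scan(model, of, ex1, ex2,
                                        n_points=config.diagonal_points,
                                        hi=config.uptake_max, lo=0.0,
                                        epsilon=config.epsilon)
    rows = []
    for pt in points:
        network_model.write_graphml(pt.subnetwork,
                                    out / f"scan_{pt.index:02d}.graphml")
        network_model.write_edge_list(pt.subnetwork,
                                      out / f"scan_{pt.index:02d}.edges.tsv")
        rows.append({"condition": pt.index, "cap": pt.cap,
                     "status": pt.solution.status,
                     "Z": pt.solution.objective_value,
                     "n_nodes": pt.subnetwork.number_of_nodes(),
                     "n_edges": pt.subnetwork.number_of_edges()})
    pd.DataFrame(rows).to_csv(out / "scan_summary.tsv", sep="\t", index=False)
    _write_manifest(out, "phase-plane", config,
                    inputs={"exchange1": ex1, "exchange2": ex2},
                    outputs=[p.name for p in sorted(out.iterdir())])
    logger.info("phase-plane: %dx%d grid, %d scan points", config.grid_points,
                config.grid_points, len(points))


def run_assess(config: PipelineConfig) -> None:
    out = _stage_dir(config, "assess")
    model = _load_model(config, "assess")
    flux_path = _require(config, "assess", "fba", "fluxes.tsv")
    fluxes_table = pd.read_csv(flux_path, sep="\t")
    flux_by_id = dict(zip(fluxes_table.reaction_id, fluxes_table.flux))
    fluxes = np.array([flux_by_id[r] for r in model.reaction_ids])
    genes_pred, enzymes_pred = assessment.predicted_active_sets(
        model, fluxes, epsilon=config.epsilon)
    genes_det = assessment.read_detection_set(
        _input_path(config, "detected_genes_path", "assess",
                    "simulate", "detected_genes.txt"))
    enzymes_det = assessment.read_detection_set(
        _input_path(config, "detected_enzymes_path", "assess",
                    "simulate", "detected_enzymes.txt"))
    scope = assessment.PathwayScope.from_tsv(
        _input_path(config, "pathway_scope_path", "assess",
                    "simulate", "pathway_scope.tsv"))
    gene_report = assessment.consistency_coefficient(genes_pred, genes_det,
                                                     scope, kind="gene")
    enzyme_report = assessment.consistency_coefficient(enzymes_pred, enzymes_det,
                                                       scope, kind="enzyme")
    gene_report.to_tsv(out / "eta_genes.tsv")
    enzyme_report.to_tsv(out / "eta_enzymes.tsv")

    scan_dir = Path(config.outdir) / "phase_plane"
    summary_path = scan_dir / "scan_summary.tsv"
    if not summary_path.exists():
        raise PipelineDependencyError(
            "stage 'assess' needs the diagonal scan — run stage 'phase-plane' first")
    n_points = len(pd.read_csv(summary_path, sep="\t"))
    node_sets = []
    for i in range(n_points):
        edges = pd.read_csv(scan_dir / f"scan_{i:02d}.edges.tsv", sep="\t",
                            header=None, names=["u", "v"])
        node_sets.append(set(edges.u) | set(edges.v))
    labels, omega = assessment.overlap_matrix(node_sets,
                                              labels=[str(i) for i in range(n_points)])
    pd.DataFrame(omega, index=labels, columns=labels).to_csv(
        out / "overlap_matrix.tsv", sep="\t")
    with open(out / "eta_summary.json", "w") as fh:
        json.dump({"eta_gene": gene_report.eta,
                   "eta_enzyme": enzyme_report.eta,
                   "gene_coverage": f"{gene_report.n_detected_predicted}/"
                                    f"{gene_report.n_predicted}",
                   "enzyme_coverage": f"{enzyme_report.n_detected_predicted}/"
                                      f"{enzyme_report.n_predicted}",
                   "min_offdiag_overlap": float(np.min(
                       omega[~np.eye(len(labels), dtype=bool)]))
                   if len(labels) > 1 else None}, fh, indent=2)
    _write_manifest(out, "assess", config, inputs={"fluxes": str(flux_path)},
                    outputs=[p.name for p in sorted(out.iterdir())])
    logger.info("assess: eta_gene=%s eta_enzyme=%s",
                gene_report.eta, enzyme_report.eta)


def run_report(config: PipelineConfig) -> None:
    out = _stage_dir(config, "report")
    summary: dict = {"package_version": __version__, "seed": config.seed}
    base = Path(config.outdir)
    for name, path in [
        ("fba", base / "fba" / "solution.json"),
        ("assessment", base / "assess" / "eta_summary.json"),
    ]:
        if path.exists():
            with open(path) as fh:
                summary[name] = json.load(fh)
    for name, path in [
        ("module_composition", base / "modules" / "composition.tsv"),
        ("module_coherence", base / "modules" / "coherence.tsv"),
        ("refinement_audit", base / "refine_of" / "audit.tsv"),
        ("scan_summary", base / "phase_plane" / "scan_summary.tsv"),
    ]:
        if path.exists():
            summary[name] = pd.read_csv(path, sep="\t").to_dict(orient="records")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    _write_manifest(out, "report", config, inputs={},
                    outputs=["summary.json"])


_RUNNERS = {
    "simulate": run_simulate,
    "fba": run_fba,
    "refine-of": run_refine_of,
    "modules": run_modules,
    "phase-plane": run_phase_plane,
    "assess": run_assess,
    "report": run_report,
}


def run(config: PipelineConfig, stage: str = "all") -> None:
    """Run one stage (or ``all`` of them in dependency order)."""
    config.validate()
    stages = list(STAGES) if stage == "all" else [stage]
    unknown = [s for s in stages if s not in _RUNNERS]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; choose from "
                         f"{STAGES + ('all',)}")
    for s in stages:
        logger.info("=== stage %s ===", s)
        _RUNNERS[s](config)
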