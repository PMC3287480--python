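"""End-to-end orchestration: sample -> core -> modules -> networks -> essentiality.

``run_fmb`` executes every stage from one config, persisting each intermediate
artifact (TSV/GraphML/JSON) into a run directory together with a
machine-readable manifest recording parameters, seeds, the filter-cascade
counts, and a SHA-256 digest of every artifact. Runs are resumable: a stage
whose artifact already exists on disk is loaded instead of recomputed. With a
fixed master seed the whole run is deterministic, so two runs of the same
config produce byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayesnet, core_selection, essentiality, modularization
from .flux_sampling import FluxMatrix, sample_flux_matrix
from .model_io import (
    ExperimentalConstraints,
    MetabolicModel,
    PerturbationSpec,
    load_constraints,
    read_model_tsv,
    read_sbml,
)

log = logging.getLogger("fmb")


@dataclass
class PipelineConfig:
    model_path: str
    constraints_path: str
    out_dir: str
    knockouts: list[str] = field(default_factory=list)
    n_per_condition: int = 1000
    p_thresh: float = 1e-2
    activity_thresh: float = 0.95
    n_perms: int = 300
    cutoff: float = 1.0
    cut_criterion: str = "inconsistent"
    bins: int = 4
    tabu_max_iter: int = 100
    tabu_len: int = 10
    tabu_restarts: int = 3
    max_parents: int = 4
    master_seed: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.p_thresh <= 1:
            raise ValueError("p_thresh must be in (0, 1]")
        if not 0 <= self.activity_thresh <= 1:
            raise ValueError("activity_thresh must be in [0, 1]")
        if self.n_perms < 1 or self.bins < 2 or self.n_per_condition < 2:
            raise ValueError("invalid sampling/clustering parameters")

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_model(path: str | Path) -> MetabolicModel:
    path = Path(path)
    if path.suffix.lower() in {".xml", ".sbml"}:
        return read_sbml(path)
    return read_model_tsv(path)


def run_fmb(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # out_dir is omitted: the manifest lives in it, and runs of the same
    # config into different directories must stay byte-identical
    params = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    manifest: dict = {"parameters": params, "counts": {}, "artifacts": {}}

    model = load_model(config.model_path)
    constraints: ExperimentalConstraints = load_constraints(config.constraints_path)
    perturbation = PerturbationSpec.from_ids(config.knockouts)
    manifest["counts"]["model_reactions"] = len(model.reactions)
    manifest["counts"]["model_metabolites"] = len(model.metabolites)

    # stage 1: flux matrix
    flux_path = out / "flux.tsv"
    if flux_path.exists():
        log.info("sample: reusing %s", flux_path)
        matrix = FluxMatrix.from_tsv(flux_path)
    else:
        log.info("sample: %d columns per condition", config.n_per_condition)
        matrix = sample_flux_matrix(model, constraints, perturbation,
                                    config.n_per_condition, config.master_seed)
        matrix.to_tsv(flux_path)
    manifest["counts"]["flux_matrix_shape"] = list(matrix.values.shape)

    # stage 2: core selection
    core_dir = out / "core"
    core_dir.mkdir(exist_ok=True)
    core = core_selection.select_core(matrix, config.p_thresh, config.activity_thresh)
    stats = pd.DataFrame({
        "reaction_id": matrix.reaction_ids,
        "p_value": [core.p_values[r] for r in matrix.reaction_ids],
        "activity_control": [core.activity["control"][r] for r in matrix.reaction_ids],
        "activity_perturbed": [core.activity["perturbed"][r] for r in matrix.reaction_ids],
        "significant": [r in set(core.significant_ids) for r in matrix.reaction_ids],
        "core": [r in set(core.core_reaction_ids) for r in matrix.reaction_ids],
    })
    rep_of = {m: rep for rep, ms in core.duplicate_groups.items() for m in ms}
    stats["duplicate_of"] = [rep_of.get(r, "") for r in matrix.reaction_ids]
    stats.to_csv(core_dir / "reaction_stats.tsv", sep="\t", index=False,
                 float_format="%.12g")
    core.reduced_matrix.to_tsv(core_dir / "reduced_flux.tsv")
    manifest["counts"]["filter_cascade"] = core.counts
    log.info("core: cascade %s", core.counts)

    # stage 3: modularization
    assignment = modularization.cluster_core_reactions(
        core.reduced_matrix.values, core.core_reaction_ids,
        n_perms=config.n_perms, cutoff=config.cutoff,
        seed=config.master_seed, criterion=config.cut_criterion)
    assignment = modularization.reinsert_duplicates(assignment, core.duplicate_groups)
    roster = pd.DataFrame(
        [{"reaction_id": r, "cluster_id": c,
          "is_duplicate": r in assignment.duplicates_of,
          "representative_id": assignment.duplicates_of.get(r, r)}
         for r, c in sorted(assignment.labels.items())])
    roster.to_csv(out / "clusters.tsv", sep="\t", index=False)
    manifest["counts"]["n_clusters"] = assignment.n_clusters
    log.info("cluster: %d modules", assignment.n_clusters)

    # stage 4: discretization shared by all network analyses
    clustered_ids = sorted(assignment.labels)
    clustered_matrix = matrix.restrict(clustered_ids)
    data = bayesnet.DiscretizedData.from_values(
        clustered_matrix.values, clustered_ids, k=config.bins)

    # stage 5: local networks + TMI/representatives
    clusters = assignment.clusters()
    local_dir = out / "local_bns"
    local_dir.mkdir(exist_ok=True)
    locals_ = bayesnet.learn_local_bns(
        clusters, data, seed=config.master_seed,
        max_iter=config.tabu_max_iter, tabu_len=config.tabu_len,
        restarts=config.tabu_restarts, max_parents=config.max_parents)
    for cid, bn in locals_.items():
        bn.write_graphml(local_dir / f"cluster_{cid:03d}.graphml")
    tmi = bayesnet.tmi_table(clusters, data)
    tmi.to_csv(out / "tmi.tsv", sep="\t", index=False, float_format="%.12g")
    reps = tmi[tmi["is_representative"]].set_index("cluster_id")["reaction_id"]
    manifest["counts"]["n_representatives"] = int(len(reps))

    # stage 6: global network
    global_bn = bayesnet.learn_global_bn(
        list(reps), data, seed=config.master_seed,
        max_iter=config.tabu_max_iter, tabu_len=config.tabu_len,
        restarts=config.tabu_restarts, max_parents=config.max_parents)
    global_bn.write_graphml(out / "global_bn.graphml")
    global_bn.write_dot(out / "global_bn.dot")
    manifest["counts"]["global_bn_arcs"] = global_bn.n_arcs
    log.info("global network: %d arcs over %d representatives",
             global_bn.n_arcs, len(reps))

    # stage 7: essentiality
    ess = essentiality.essentiality_table(model, constraints, assignment=assignment)
    ess.to_csv(out / "essentiality.tsv", sep="\t", index=False, float_format="%.12g")
    summary = essentiality.essentiality_summary(ess)
    summary.to_csv(out / "essentiality_summary.tsv", sep="\t", index=False,
                   float_format="%.12g")
    for condition in ("control", "perturbed"):
        sub = summary[(summary["condition"] == condition)]
        manifest["counts"][f"mean_essentiality_all_{condition}"] = float(
            sub[sub["scope"] == "all"]["mean_essentiality"].iloc[0])
        clustered = sub[sub["scope"] == "clustered"]
        if len(clustered):
            manifest["counts"][f"mean_essentiality_clustered_{condition}"] = float(
                clustered["mean_essentiality"].iloc[0])

    for artifact in sorted(out.rglob("*")):
        if artifact.is_file() and artifact.name != "manifest.json":
            manifest["artifacts"][str(artifact.relative_to(out))] = _sha256(artifact)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    write_reports(out)
    return out


def write_reports(run_dir: str | Path) -> Path:
    """Human-readable per-module summary assembled from the run artifacts."""
    run_dir = Path(run_dir)
    required = {"manifest": run_dir / "manifest.json", "tmi": run_dir / "tmi.tsv",
                "clusters": run_dir / "clusters.tsv",
                "essentiality": run_dir / "essentiality.tsv"}
    for stage, path in required.items():
        if not path.exists():
            raise FileNotFoundError(f"missing artifact {path}; rerun stage {stage!r}")
    manifest = json.loads(required["manifest"].read_text())
    tmi = pd.read_csv(required["tmi"], sep="\t")
    ess = pd.read_csv(required["essentiality"], sep="\t")
    lines = ["FMB run summary", "===============", ""]
    lines.append(f"filter cascade: {manifest['counts'].get('filter_cascade')}")
    lines.append(f"modules: {manifest['counts'].get('n_clusters')}")
    lines.append(f"global network arcs: {manifest['counts'].get('global_bn_arcs')}")
    lines.append("")
    ess_by = ess.groupby(["cluster_id", "condition"])["essentiality"].mean()
    for cid, sub in tmi.groupby("cluster_id"):
        means = []
        for condition in ("control", "perturbed"):
            try:
                means.append(f"{ess_by.loc[(cid, condition)]:.3f}")
            except KeyError:
                pass
        lines.append(f"cluster {cid} (mean essentiality {'/'.join(means)}):")
        for _, row in sub.sort_values(["tmi_bits", "reaction_id"],
                                      ascending=[False, True]).iterrows():
            marker = " *" if row["is_representative"] else ""
            lines.append(f"  {row['reaction_id']}: TMI {row['tmi_bits']:.4f} bits{marker}")
    report = run_dir / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    return report
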