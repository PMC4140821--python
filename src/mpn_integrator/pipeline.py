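"""End-to-end workflows with YAML config, logging and run manifests.

Two workflows are orchestrated: ``dock-filter`` (score, filter, re-rank and
cluster a pose set under experimental constraints) and ``assembly-audit``
(per-subunit rigid map fitting, cross-link auditing and optional restrained
flexible fitting). Every run writes a manifest recording the package
version, the seed, and a hash of the resolved configuration so identical
manifests imply identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .conservation import conservation_profile, map_profile, read_alignment
from .crosslinks import filter_links, read_links
from .docking import ConstraintSet, PoseSet, cluster_poses, filter_poses, rank_poses, read_zdock_table
from .errors import PipelineError
from .density import read_map
from .refine import assess_model, flexible_fit
from .structure_io import apply_pose, read_structure, write_structure

log = logging.getLogger("mpn_integrator")

KNOWN_KEYS = {
    "workflow", "receptor", "ligand", "poses", "model", "map", "links", "alignment",
    "reference_id", "conservation_chain", "resolution", "chain_map", "constraints",
    "weights", "seed", "output_dir", "rmsd_cutoff", "refine", "cycles", "n_points",
}


@dataclass
class RunConfig:
    workflow: str
    output_dir: Path
    seed: int = 0
    options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - KNOWN_KEYS
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "workflow" not in raw or "output_dir" not in raw:
            raise PipelineError("config requires 'workflow' and 'output_dir'")
        wf = raw.pop("workflow")
        out = Path(raw.pop("output_dir"))
        seed = int(raw.pop("seed", 0))
        for key in ("receptor", "ligand", "poses", "model", "map", "links", "alignment"):
            if key in raw and not Path(raw[key]).exists():
                raise PipelineError(f"config file for {key!r} does not exist: {raw[key]}")
        return cls(wf, out, seed, raw)

    def digest(self) -> str:
        blob = json.dumps(
            {"workflow": self.workflow, "seed": self.seed,
             "options": {k: str(v) for k, v in sorted(self.options.items())}},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, outdir: Path, extra: dict) -> None:
    manifest = {
        "tool": "mpn-integrator",
        "version": __version__,
        "workflow": cfg.workflow,
        "seed": cfg.seed,
        "config_hash": cfg.digest(),
        "options": {k: str(v) for k, v in sorted(cfg.options.items())},
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _load_constraints(spec, receptor, ligand) -> ConstraintSet:
    """Constraint block → ConstraintSet; residues given as 'CHAIN:SEQID'."""
    def keys(items):
        out = set()
        for it in items or []:
            chain, seq = str(it).split(":")
            out.add((chain, int(seq), None))
        return out

    spec = spec or {}
    return ConstraintSet(
        passive_residues=keys(spec.get("passive")),
        required_receptor=keys(spec.get("required_receptor")),
        required_ligand=keys(spec.get("required_ligand")),
        buried_area_window=tuple(spec.get("buried_area_window", (1200.0, 1800.0))),
        sc_min=float(spec.get("sc_min", 0.5)),
        passive_tolerance=int(spec.get("passive_tolerance", 0)),
    )


def run_dock_filter(cfg: RunConfig, pose_set: PoseSet | None = None,
                    constraints: ConstraintSet | None = None):
    """Score/filter/re-rank/cluster a pose set; write table, clusters and
    top-pose PDBs. `pose_set`/`constraints` may be passed directly (library
    use) or resolved from config paths."""
    outdir = cfg.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    opts = cfg.options
    stage = "load-inputs"
    try:
        if pose_set is None:
            receptor = read_structure(opts["receptor"])
            ligand = read_structure(opts["ligand"])
            pose_set = read_zdock_table(opts["poses"], receptor, ligand)
        if constraints is None:
            constraints = _load_constraints(opts.get("constraints"), pose_set.receptor, pose_set.ligand)
        conservation_scores = None
        if opts.get("alignment"):
            stage = "conservation"
            aln = read_alignment(opts["alignment"])
            prof = conservation_profile(aln)
            chain = opts.get("conservation_chain") or pose_set.receptor.chain_ids[0]
            mapped = map_profile(prof, aln, opts["reference_id"], pose_set.receptor, chain)
            conservation_scores = {(chain, sid, None): v for sid, v in mapped.items()}
        stage = "filter"
        table = filter_poses(
            pose_set, constraints,
            n_points=int(opts.get("n_points", 240)),
            conservation_scores=conservation_scores,
        )
        stage = "rank"
        table = rank_poses(table, opts.get("weights"), constraints.buried_area_window)
        stage = "cluster"
        table, leaders = cluster_poses(pose_set, table, float(opts.get("rmsd_cutoff", 5.0)))
        stage = "write-artifacts"
        table.to_csv(outdir / "pose_scores.tsv", sep="\t", index=False)
        by_id = {p.pose_id: p for p in pose_set.poses}
        for pid in leaders[:5]:
            posed = apply_pose(pose_set.ligand, by_id[pid])
            write_structure(posed, outdir / f"pose_{pid:04d}_ligand.pdb")
        _write_manifest(cfg, outdir, {"n_poses": len(pose_set.poses),
                                      "n_passing": int(table["passes"].sum()),
                                      "n_clusters": int(table["cluster"].nunique())})
        return table, leaders
    except Exception as exc:
        for f in outdir.glob("pose_*.pdb"):
            f.unlink()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"dock-filter failed at stage {stage!r}: {exc}") from exc


def run_assembly_audit(cfg: RunConfig, model=None, density=None, links=None):
    """Audit (and optionally refine) an assembly model against a map and
    cross-link table; writes report.json and, when refining, the refined
    model."""
    outdir = cfg.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    opts = cfg.options
    stage = "load-inputs"
    try:
        if model is None:
            model = read_structure(opts["model"])
        if density is None:
            density = read_map(opts["map"], resolution=float(opts.get("resolution", 25.0)))
        if density.resolution is None:
            density.resolution = float(opts.get("resolution", 25.0))
        if links is None:
            links = filter_links(read_links(opts["links"]))
        chain_map = opts.get("chain_map") or {}
        stage = "assess-initial"
        before = assess_model(model, density, links, chain_map)
        report = {
            "initial": {
                "local_ccc": before["local_ccc"],
                "mean_link_distance": before["link_audit"].mean_all,
                "mean_link_distance_excl_outliers": before["link_audit"].mean_excl_outliers,
                "n_satisfied": before["link_audit"].n_satisfied,
                "n_outliers": before["link_audit"].n_outliers,
            }
        }
        final_model = model
        if opts.get("refine"):
            stage = "flexible-fit"
            trace = flexible_fit(
                model, density, links, chain_map,
                cycles=int(opts.get("cycles", 500)), seed=cfg.seed,
            )
            final_model = trace.final_model
            stage = "assess-refined"
            after = assess_model(final_model, density, links, chain_map)
            report["refined"] = {
                "local_ccc": after["local_ccc"],
                "mean_link_distance": after["link_audit"].mean_all,
                "mean_link_distance_excl_outliers": after["link_audit"].mean_excl_outliers,
                "n_satisfied": after["link_audit"].n_satisfied,
                "n_outliers": after["link_audit"].n_outliers,
            }
            write_structure(final_model, outdir / "refined_model.pdb")
        stage = "write-artifacts"
        before["link_audit"].to_frame().to_csv(outdir / "link_audit.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        _write_manifest(cfg, outdir, {"n_links": len(links)})
        return report
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"assembly-audit failed at stage {stage!r}: {exc}") from exc
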