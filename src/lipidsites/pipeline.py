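"""The umbrella pipeline: contacts → sites → annotate (→ rules).

Each stage writes CSV/JSON files stamped with the package version, the
config hash and the seed, so a run can be reproduced from its own outputs.
All randomness (community detection) flows from ``config.seed``; outputs
are byte-identical across runs with the same config and inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, annotate, contacts, io, rules, sites
from .config import PipelineConfig
from .core import SystemTopology, Trajectory

__all__ = ["run_pipeline", "run_rules_stage"]

logger = logging.getLogger(__name__)


def _stamp(config: PipelineConfig) -> str:
    return f"# lipidsites v{__version__} config={config.config_hash} seed={config.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(config))
        df.to_csv(fh, index=False, lineterminator="\n")


def _write_json(obj, path: Path, config: PipelineConfig) -> None:
    doc = {
        "producer": f"lipidsites v{__version__}",
        "config_hash": config.config_hash,
        "seed": config.seed,
        "payload": obj,
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))


def run_rules_stage(
    points, config: PipelineConfig, outdir: Path
) -> list[rules.RuleReport]:
    params = rules.RuleParams(
        adjacency_cutoff=config.adjacency_cutoff,
        z_tolerance=config.rule_z_tolerance,
        depth_center=config.rule_depth_center,
        depth_halfwidth=config.rule_depth_halfwidth,
        aromatic_depth_margin=config.rule_aromatic_margin,
        expansion_radius=config.rule_expansion_radius,
        include_tyr=config.rule_include_tyr,
    )
    reports = rules.scan_structure(points, config.membrane_center_z, params)
    rows = [r.to_dict() for r in reports]
    df = pd.DataFrame(
        [
            {
                "rank": k + 1,
                "residues": ";".join(str(i) for i in sorted(r.residue_ids)),
                "rules_passed": r.overall,
                "rule1_basics": r.rule1_basics,
                "rule2_polar": r.rule2_polar,
                "rule3_aromatic": r.rule3_aromatic,
                "n_basics_in_cluster": r.n_basics_in_cluster,
                "max_pairwise_distance_nm": r.max_pairwise_distance,
                "max_z_separation_nm": r.max_z_separation,
                "mean_depth_nm": r.mean_depth,
                "has_gly": r.has_gly,
            }
            for k, r in enumerate(reports)
        ]
    )
    _write_csv(df, outdir / "rules.csv", config)
    _write_json(rows, outdir / "rules.json", config)
    return reports


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    system: tuple[SystemTopology, Trajectory] | None = None,
) -> dict:
    """Execute the configured stages and write the report bundle.

    ``system`` may pass an in-memory (topology, trajectory) pair; otherwise
    the configured structure/trajectory paths are loaded. With a structure
    but no trajectory only the rules stage runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    bundle: dict = {"outdir": str(outdir), "config_hash": config.config_hash}

    if system is not None:
        topo, traj = system
    elif config.structure and config.trajectory:
        topo, traj = io.load_system(
            config.structure,
            config.trajectory,
            stride=config.stride,
            dt_ns=config.dt_ns,
        )
    elif config.structure:
        # rules-only run on a static structure
        topo, traj = io.load_system(config.structure, dt_ns=config.dt_ns)
        points = rules.residue_points_from_topology(topo, traj.coords[0])
        bundle["rules"] = run_rules_stage(points, config, outdir)
        return bundle
    else:
        raise ValueError("config must name a structure (and usually a trajectory)")

    try:
        # ---- contacts stage ------------------------------------------------
        propensity = contacts.lipid_binding_propensity(
            traj, topo, cutoff=config.contact_cutoff, equilibration_skip=config.skip_fraction
        )
        _write_csv(propensity, outdir / "propensity.csv", config)
        counts, edges, ztable = contacts.contacting_residue_z_profile(
            traj,
            topo,
            cutoff=config.contact_cutoff,
            min_contact_probability=config.min_contact_probability,
            residue_filter=set(config.z_profile_residues) or None,
            bin_width=config.z_bin_width,
        )
        zdf = pd.DataFrame(
            {"z_low": edges[:-1], "z_high": edges[1:], "count": counts}
        )
        _write_csv(zdf, outdir / "z_profile.csv", config)
        _write_csv(ztable, outdir / "z_profile_residues.csv", config)
        profile = contacts.bead_residue_profile(
            traj, topo, lipid_type=config.lipid_type, cutoff=config.contact_cutoff
        )
        _write_csv(
            profile.reset_index(names="bead_role"), outdir / "bead_profile.csv", config
        )
        bundle["propensity"] = propensity
    except Exception as e:
        raise RuntimeError(f"contacts stage failed: {e}") from e

    try:
        # ---- sites stage ---------------------------------------------------
        found, bound = sites.find_binding_sites(
            traj,
            topo,
            lipid_type=config.lipid_type,
            lower=config.lower_cutoff,
            upper=config.upper_cutoff,
            min_residence=config.min_residence_ns,
            residue_occupancy_floor=config.residue_occupancy_floor,
            weight_threshold=config.edge_weight_threshold,
            residence_estimator=config.residence_estimator,
            seed=config.seed,
        )
        _write_json([s.to_dict() for s in found], outdir / "sites.json", config)
        sdf = pd.DataFrame(
            [
                {
                    "site_id": s.site_id,
                    "residues": ";".join(str(r) for r in sorted(s.residue_ids)),
                    "n_residues": len(s.residue_ids),
                    "occupancy": s.occupancy,
                    "residence_time_ns": s.residence_time,
                    "n_events": len(s.events),
                }
                for s in found
            ]
        )
        _write_csv(sdf, outdir / "sites.csv", config)
        for s in found:
            if s.representative_pose is not None:
                frame, _lip = s.representative_pose
                io.write_pose_pdb(
                    topo, traj, frame, outdir / f"site_{s.site_id}_pose.pdb"
                )
        bundle["sites"] = found
    except Exception as e:
        raise RuntimeError(f"sites stage failed: {e}") from e

    try:
        # ---- annotate stage --------------------------------------------------
        coords0 = traj.coords[0]
        anns = [
            annotate.annotate_site(s, topo, coords0, cutoff=config.adjacency_cutoff)
            for s in found
        ]
        _write_csv(
            pd.DataFrame([a.as_row() for a in anns]) if anns else pd.DataFrame(),
            outdir / "annotations.csv",
            config,
        )
        if found:
            strata, contrasts = annotate.stratify_occupancies(
                found, anns, test=config.ttest, adjust=config.adjust
            )
            _write_csv(strata, outdir / "strata.csv", config)
            _write_csv(contrasts, outdir / "contrasts.csv", config)
            bundle["strata"] = strata
        bundle["annotations"] = anns
    except Exception as e:
        raise RuntimeError(f"annotate stage failed: {e}") from e

    if config.structure:
        points = rules.residue_points_from_topology(topo, traj.coords[0])
        bundle["rules"] = run_rules_stage(points, config, outdir)
    return bundle
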