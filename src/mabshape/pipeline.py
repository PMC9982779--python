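"""End-to-end orchestration of the two analysis workflows.

``cmd`` mode (plain-MD ensembles): Fab angles → shape fractions → CH2
distance → GROMOS clustering with medoid export.

``amd`` mode (boosted ensembles): Fab angles → Maclaurin-reweighted
(θ1, θ2) free-energy surface → minimum-energy frame set → Δϕ, ED-filtered
Δϕ, CH2/glycan distances, LC–hinge contacts, H-bonds, glycosidic torsions
and glycan clustering, all restricted to the minimum-energy frames.

Outputs are tidy CSVs plus medoid PDBs and a JSON manifest recording every
threshold, path and seed, so any output table is reproducible from the
manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amd import default_theta_edges, reweight_fes, select_min_energy_frames
from .clustering import essential_dynamics, filtered_delta_phi, gromos_cluster, rmsd_matrix
from .descriptors import (
    basic_descriptors,
    ch2_distance,
    glycan_com_displacement,
    glycan_min_distance,
    glycosidic_dihedrals,
    hydrogen_bonds,
    residue_contacts,
)
from .geometry import classify_shape, compute_delta_phi, compute_fab_angles
from .groups import AtomGroupConfig, load_groups
from .io import TrajectoryEnsemble, load_ensemble, parse_boost_log

log = logging.getLogger("mabshape")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one analysis run depends on, in one record."""

    topology: str | None = None
    trajectories: list = field(default_factory=list)
    groups: str | AtomGroupConfig | None = None
    mode: str = "cmd"  # 'cmd' or 'amd'
    exclude_frames: int = 0
    keep_last: int | None = None
    stride: int = 1
    boost_log: str | None = None
    temperature: float = 300.0
    shape_threshold: float = 85.0  # deg
    pmf_cutoff: float = 0.5  # kcal/mol
    contact_cutoff: float = 0.4  # nm
    bin_width: float = 2.5  # deg
    k_max: int = 10
    cluster_cutoff: float | None = None  # nm; default 0.75 (cmd) / 0.65 (amd)
    max_clusters: int | None = None  # default 15 (cmd) / 10 (amd)
    glycan_cluster_cutoff: float = 0.1  # nm
    glycan_max_clusters: int = 10
    ed_components: tuple[int, ...] = (0, 1)
    linkages: list = field(default_factory=list)
    outdir: str = "mabshape_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("cmd", "amd"):
            raise ValueError("mode must be 'cmd' or 'amd'")
        if self.cluster_cutoff is None:
            self.cluster_cutoff = 0.75 if self.mode == "cmd" else 0.65
        if self.max_clusters is None:
            self.max_clusters = 15 if self.mode == "cmd" else 10
        if self.mode == "amd" and self.boost_log is None and not self.trajectories:
            pass  # in-memory runs may pass the boost record directly


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            log.error("stage %s: FAILED after %.2fs: %s", self.name, dt, exc)
            raise RuntimeError(f"pipeline stage '{self.name}' failed: {exc}") from exc
        log.info("stage %s: done in %.2fs", self.name, dt)


def run_pipeline(
    config: PipelineConfig,
    ensemble: TrajectoryEnsemble | None = None,
    boost=None,
    groups: AtomGroupConfig | None = None,
) -> dict:
    """Run the configured workflow; returns the report dict (also written
    to ``<outdir>/manifest.json``).

    *ensemble*, *boost* and *groups* may be passed in-memory; otherwise they
    are loaded from the paths in *config*.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "thresholds": {
            "shape_threshold_deg": config.shape_threshold,
            "pmf_cutoff_kcalmol": config.pmf_cutoff,
            "contact_cutoff_nm": config.contact_cutoff,
            "cluster_cutoff_nm": config.cluster_cutoff,
            "max_clusters": config.max_clusters,
            "glycan_cluster_cutoff_nm": config.glycan_cluster_cutoff,
            "glycan_max_clusters": config.glycan_max_clusters,
            "bin_width_deg": config.bin_width,
            "k_max": config.k_max,
            "temperature_K": config.temperature,
        },
    }

    with _Stage("load"):
        if ensemble is None:
            ensemble = load_ensemble(
                config.trajectories,
                topology=config.topology,
                exclude_frames=config.exclude_frames,
                keep_last=config.keep_last,
                stride=config.stride,
            )
        if groups is None:
            if config.groups is None:
                raise ValueError("an atom-group config is required")
            groups = (
                config.groups
                if isinstance(config.groups, AtomGroupConfig)
                else load_groups(config.groups, topology=ensemble.traj.topology)
            )
        counts = np.bincount(ensemble.replica)
        report["replicas"] = {
            "n_replicas": int(len(counts)),
            "frames_per_replica": counts.tolist(),
            "n_frames": int(ensemble.n_frames),
            "sources": ensemble.sources,
        }
        log.info("loaded %d frames from %d replica(s)", ensemble.n_frames, len(counts))

    with _Stage("angles"):
        angles = compute_fab_angles(ensemble, groups)
        shape = classify_shape(angles, threshold=config.shape_threshold)
        dphi = compute_delta_phi(angles)
        df = angles.to_frame()
        df["dphi1"] = dphi.dphi1
        df["dphi2"] = dphi.dphi2
        df["shape_label"] = shape.labels
        _write_csv(df, out / "angles.csv")
        report["shape_fractions"] = {
            "T": shape.fraction_t,
            "Y": shape.fraction_y,
            "asym": shape.fraction_asym,
            "fab1_T": shape.per_fab_fraction_t[0],
            "fab2_T": shape.per_fab_fraction_t[1],
        }

    with _Stage("basic_descriptors"):
        rmsd, rmsf, rg = basic_descriptors(ensemble)
        _write_csv(
            pd.DataFrame(
                {"frame": np.arange(len(rmsd)), "rmsd_nm": rmsd, "rg_nm": rg}
            ),
            out / "rmsd_rg.csv",
        )
        _write_csv(
            pd.DataFrame({"atom": np.arange(len(rmsf)), "rmsf_nm": rmsf}),
            out / "rmsf.csv",
        )

    with _Stage("ch2_distance"):
        ch2 = ch2_distance(ensemble, groups)
        _write_csv(ch2.to_frame(), out / "ch2_distance.csv")
        q1, med, q3 = ch2.quartiles
        report["ch2_distance_nm"] = {"median": med, "q1": q1, "q3": q3}

    if config.mode == "amd":
        _run_amd_branch(config, ensemble, groups, angles, boost, out, report)
    else:
        with _Stage("clustering"):
            mat = rmsd_matrix(ensemble)
            clusters = gromos_cluster(
                mat, cutoff=config.cluster_cutoff, max_clusters=config.max_clusters
            )
            _write_cluster_outputs(clusters, ensemble, out, "protein")
            report["clusters"] = _cluster_summary(clusters)

    report["outputs"] = sorted(p.name for p in out.iterdir() if p.is_file())
    (out / "manifest.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _cluster_summary(clusters) -> dict:
    return {
        "n_clusters": int(clusters.n_clusters),
        "populations": clusters.populations.tolist(),
        "medoid_frames": clusters.medoids.tolist(),
        "unassigned_fraction": clusters.unassigned_fraction,
    }


def _write_cluster_outputs(clusters, ensemble, out: Path, tag: str) -> None:
    _write_csv(
        pd.DataFrame(
            {"frame": np.arange(len(clusters.labels)), "cluster": clusters.labels}
        ),
        out / f"clusters_{tag}.csv",
    )
    for k, m in enumerate(clusters.medoids):
        ensemble.traj[int(m)].save_pdb(str(out / f"medoid_{tag}_{k}.pdb"))


def _run_amd_branch(config, ensemble, groups, angles, boost, out: Path, report: dict):
    with _Stage("reweight_fes"):
        if boost is None:
            if config.boost_log is None:
                raise ValueError("amd mode requires a boost log or BoostRecord")
            boost = parse_boost_log(config.boost_log, temperature=config.temperature)
        edges = default_theta_edges(config.bin_width)
        grid = reweight_fes(angles, boost, edges, edges, k_max=config.k_max)
        _write_csv(grid.to_frame(), out / "fes.csv")
        report["fes"] = {
            "minimum_theta1": grid.minimum()[0],
            "minimum_theta2": grid.minimum()[1],
            "series_max_rel_err": grid.series_max_rel_err,
        }

    with _Stage("min_energy_frames"):
        min_frames = select_min_energy_frames(grid, angles, cutoff=config.pmf_cutoff)
        np.savetxt(out / "minframes.txt", min_frames, fmt="%d")
        report["min_energy_frames"] = {
            "count": int(len(min_frames)),
            "fraction": float(len(min_frames) / len(angles)),
        }

    with _Stage("delta_phi"):
        sub = angles.take(min_frames)
        dphi = compute_delta_phi(sub)
        _write_csv(
            pd.DataFrame(
                {"frame": min_frames, "dphi1": dphi.dphi1, "dphi2": dphi.dphi2}
            ),
            out / "delta_phi_min_energy.csv",
        )

    with _Stage("essential_dynamics"):
        ed = essential_dynamics(ensemble, selection=np.arange(ensemble.traj.n_atoms))
        cum = ed.cumulative_variance
        _write_csv(
            pd.DataFrame(
                {
                    "component": np.arange(len(ed.eigenvalues)),
                    "eigenvalue_nm2": ed.eigenvalues,
                    "cumulative_variance": cum,
                }
            ),
            out / "ed_spectrum.csv",
        )
        report["ed"] = {"top2_variance_fraction": float(cum[1]) if len(cum) > 1 else 1.0}
        rows = []
        for comp in config.ed_components:
            fd = filtered_delta_phi(ed, groups, [comp], min_energy_frames=min_frames)
            rows.append(
                pd.DataFrame(
                    {
                        "frame": min_frames,
                        "component": comp + 1,
                        "dphi1": fd.dphi1,
                        "dphi2": fd.dphi2,
                    }
                )
            )
        _write_csv(pd.concat(rows, ignore_index=True), out / "delta_phi_filtered.csv")

    sub_traj = TrajectoryEnsemble(
        traj=ensemble.traj[min_frames], replica=ensemble.replica[min_frames]
    )

    with _Stage("glycan_descriptors"):
        if groups.glycan_a.size and groups.glycan_b.size:
            mind = glycan_min_distance(sub_traj, groups)
            _write_csv(mind.to_frame(), out / "glycan_min_distance.csv")
            report["glycan_min_distance_nm"] = {"median": mind.median}
            for chain in "ab":
                com = glycan_com_displacement(sub_traj, groups, chain=chain)
                _write_csv(com.to_frame(), out / f"glycan_com_{chain}.csv")

    with _Stage("contacts"):
        if groups.lc_cterm.size:
            table = residue_contacts(sub_traj, groups, cutoff=config.contact_cutoff)
            _write_csv(table.to_frame(), out / "contacts_lc_hinge.csv")
            report["contacts_mean_per_residue"] = table.mean_per_residue().to_dict()

    with _Stage("hbonds"):
        try:
            hb = hydrogen_bonds(sub_traj)
            _write_csv(hb.table, out / "hbonds.csv")
            report["hbonds"] = {"n_pairs": int(len(hb.table))}
        except ValueError as err:
            report["hbonds"] = {"skipped": str(err)}
            log.warning("hbonds skipped: %s", err)

    with _Stage("dihedrals"):
        if config.linkages:
            dih = glycosidic_dihedrals(sub_traj, config.linkages)
            _write_csv(dih.to_frame(), out / "glycosidic_dihedrals.csv")
            report["dihedrals_in_range"] = {
                name: {"phi": float(dih.phi_in_range[k]), "psi": float(dih.psi_in_range[k])}
                for k, name in enumerate(dih.linkage_names)
            }

    with _Stage("glycan_clustering"):
        if groups.glycan_a.size:
            for chain in "ab":
                sel = getattr(groups, f"glycan_{chain}")
                oxy = [
                    int(i)
                    for i in sel
                    if sub_traj.traj.topology.atom(int(i)).name.startswith("O")
                ]
                if len(oxy) < 3:
                    continue
                mat = rmsd_matrix(sub_traj, selection=np.asarray(oxy))
                clusters = gromos_cluster(
                    mat,
                    cutoff=config.glycan_cluster_cutoff,
                    max_clusters=config.glycan_max_clusters,
                )
                _write_cluster_outputs(clusters, sub_traj, out, f"glycan_{chain}")
                report[f"glycan_{chain}_clusters"] = _cluster_summary(clusters)

    with _Stage("protein_clustering"):
        mat = rmsd_matrix(sub_traj)
        clusters = gromos_cluster(
            mat, cutoff=config.cluster_cutoff, max_clusters=config.max_clusters
        )
        _write_cluster_outputs(clusters, sub_traj, out, "protein")
        report["clusters"] = _cluster_summary(clusters)
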