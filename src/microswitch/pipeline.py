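"""End-to-end orchestration with file interchange between stages.

Each stage consumes only files produced by earlier stages (enabling
resume-from-stage) and every produced artifact is recorded in a manifest
with its SHA-256 hash, so a rerun with the same config and inputs can be
verified byte-for-byte for the deterministic stages.

One global seed is fanned out per stage as ``(seed + crc32(stage)) mod
2^31`` so adding a stage never shifts the randomness of earlier ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import conditional, ecc as ecc_mod, kinetics as kin_mod, microstates, rotamers, synthetic, trajio

logger = logging.getLogger("microswitch")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "stage_seed"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def stage_seed(seed: int, stage: str) -> int:
    return (seed + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Either ``synthetic`` holds a SyntheticSpec-shaped mapping, or
    ``topology``/``trajectories`` point at input files. One seed governs
    every stochastic stage.
    """

    outdir: str = "out"
    seed: int = 0
    synthetic: dict | None = None
    topology: str | None = None
    trajectories: list[tuple[str, str]] | None = None  # (path, label)
    n_components: int = 20
    cluster_dims: int = 5
    k_range: tuple[int, ...] = (4, 5, 6)
    minor_threshold: float = 0.05
    contact_cutoff: float = 4.0
    dwell_dominance: float = 0.9
    dwell_min_length: int | None = None  # default: third of a replica
    conditioning_residue: int | None = None  # default: highest-ECC residue
    ecc_label: str | None = None  # ensemble analyzed for coupling; default first
    histogram_bins: int = 100
    oblique_angle: float = 60.0
    kinetics: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.synthetic is None and (self.topology is None or not self.trajectories):
            raise PipelineError(
                "config", "no-input", "config needs either a synthetic spec or input paths"
            )
        if not 0.5 < self.dwell_dominance <= 1.0:
            raise PipelineError("config", "bad-dominance", "dominance must be in (0.5, 1]")
        if self.trajectories is not None:
            self.trajectories = [tuple(t) for t in self.trajectories]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: str, seed: int):
        self.outdir = outdir
        self.data = {"seed": seed, "stages": {}, "status": "running"}

    def record(self, stage: str, paths: dict[str, str], t0: float) -> None:
        self.data["stages"][stage] = {
            "wall_time_s": round(time.time() - t0, 3),
            "outputs": {k: {"path": p, "sha256": _sha256(p)} for k, p in paths.items()},
        }
        logger.info("stage=%s wall=%.2fs outputs=%d", stage, time.time() - t0, len(paths))

    def finish(self, status: str) -> str:
        self.data["status"] = status
        path = os.path.join(self.outdir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)
        return path


# ---------------------------------------------------------------------------
# Stages


def _load(config: PipelineConfig, dataset_dir: str | None):
    if config.synthetic is not None:
        files = sorted(os.listdir(dataset_dir))
        trajs = [
            (os.path.join(dataset_dir, f), f.split("_")[1])
            for f in files
            if f.startswith("traj_") and f.endswith(".dcd")
        ]
        return trajio.load_ensemble(os.path.join(dataset_dir, "topology.pdb"), trajs)
    return trajio.load_ensemble(config.topology, config.trajectories)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest dict.

    Any stage error aborts with a PipelineError naming the stage; partial
    outputs are retained under a manifest marked "failed".
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    manifest = _Manifest(config.outdir, config.seed)
    scheme = rotamers.build_default_scheme()

    try:
        # -- generate ------------------------------------------------------
        dataset_dir = None
        if config.synthetic is not None:
            t0 = time.time()
            dataset_dir = os.path.join(config.outdir, "dataset")
            spec_kwargs = dict(config.synthetic)
            spec_kwargs["seed"] = stage_seed(config.seed, "generate")
            if "coupled_residues" in spec_kwargs:
                spec_kwargs["coupled_residues"] = [
                    tuple(c) for c in spec_kwargs["coupled_residues"]
                ]
            spec = synthetic.SyntheticSpec(**spec_kwargs)
            paths = synthetic.write_dataset(spec, dataset_dir)
            manifest.record("generate", paths, t0)

        # -- load + superpose + pca ---------------------------------------
        t0 = time.time()
        try:
            ensemble = _load(config, dataset_dir)
        except (trajio.FormatError, IOError) as exc:
            raise PipelineError("load", "io", str(exc)) from exc
        backbone = trajio.superpose(trajio.extract_backbone(ensemble))
        model = microstates.fit_shared_pca(backbone, config.n_components)
        scores = microstates.project(model, backbone)

        model_path = os.path.join(config.outdir, "pca_model.npz")
        np.savez(
            model_path,
            mean=model.mean,
            components=model.components,
            explained_variance=model.explained_variance,
        )
        scores_path = os.path.join(config.outdir, "pca_scores.csv")
        sdf = scores.labels.copy()
        for i in range(min(scores.scores.shape[1], config.cluster_dims)):
            sdf[f"pc{i}"] = scores.scores[:, i]
        sdf.to_csv(scores_path, index=False, float_format="%.6f")
        rmsf_path = os.path.join(config.outdir, "rmsf.csv")
        trajio.rmsf_per_residue(backbone).to_csv(rmsf_path, index=False, float_format="%.6f")
        manifest.record(
            "pca", {"model": model_path, "scores": scores_path, "rmsf": rmsf_path}, t0
        )

        # -- cluster -------------------------------------------------------
        t0 = time.time()
        assignments = {}
        cl_rows, summary_rows = [], []
        for label in ensemble.labels:
            sub = scores.subset(label)
            a = microstates.cluster_ensemble(
                sub,
                k_range=config.k_range,
                n_dims=config.cluster_dims,
                seed=stage_seed(config.seed, "cluster"),
            )
            assignments[label] = (a, sub)
            df = sub.labels.copy()
            df["cluster"] = a.assignments
            cl_rows.append(df)
            for c in range(a.k):
                summary_rows.append(
                    {
                        "label": label,
                        "cluster": c,
                        "population_pct": a.populations[c],
                        "medoid_replica": a.medoids[c][0],
                        "medoid_frame": a.medoids[c][1],
                        **{f"center_pc{d}": a.centers[c, d] for d in range(config.cluster_dims)},
                    }
                )
        clusters_path = os.path.join(config.outdir, "clusters.csv")
        pd.concat(cl_rows).to_csv(clusters_path, index=False)
        cluster_summary_path = os.path.join(config.outdir, "cluster_summary.csv")
        pd.DataFrame(summary_rows).to_csv(
            cluster_summary_path, index=False, float_format="%.6f"
        )
        rmsd_mat, rmsd_names = microstates.cluster_center_rmsd(
            [a for a, _ in assignments.values()], model
        )
        rmsd_path = os.path.join(config.outdir, "cluster_center_rmsd.csv")
        pd.DataFrame(
            rmsd_mat,
            index=[f"{l}:{c}" for l, c in rmsd_names],
            columns=[f"{l}:{c}" for l, c in rmsd_names],
        ).to_csv(rmsd_path, float_format="%.4f")
        cluster_outputs = {
            "assignments": clusters_path,
            "summary": cluster_summary_path,
            "center_rmsd": rmsd_path,
        }
        for label, (a, _sub) in assignments.items():
            for c in range(a.k):
                rep_id, frame = a.medoids[c]
                rep = next(
                    r for r in ensemble.replicas
                    if r.label == label and r.replica_id == rep_id
                )
                med_path = os.path.join(config.outdir, f"medoid_{label}_c{c}.pdb")
                trajio.write_topology_pdb(ensemble.topology, rep.coords[frame], med_path)
                cluster_outputs[f"medoid:{label}:{c}"] = med_path
        manifest.record("cluster", cluster_outputs, t0)

        # -- chi / rotamers ------------------------------------------------
        t0 = time.time()
        chi_residues = [
            i
            for i, name in enumerate(ensemble.topology.residue_names)
            if name in scheme.residue_schemes
        ]
        chi_series = rotamers.compute_chi(ensemble, chi_residues)
        state_series = [rotamers.assign_states(c, scheme) for c in chi_series]

        chi_path = os.path.join(config.outdir, "chi.csv")
        cdf = chi_series[0].labels.copy()
        for c in chi_series:
            cdf[f"chi1_res{c.residue_index}"] = c.chi1
            if c.chi2 is not None:
                cdf[f"chi2_res{c.residue_index}"] = c.chi2
        cdf.to_csv(chi_path, index=False, float_format="%.3f")

        states_path = os.path.join(config.outdir, "rotamer_states.csv")
        rdf = chi_series[0].labels.copy()
        for s in state_series:
            rdf[f"state_res{s.residue_index}"] = s.states
        rdf.to_csv(states_path, index=False)

        summary_path = os.path.join(config.outdir, "rotamer_summary.csv")
        pd.concat(
            [
                rotamers.state_summary(s, config.minor_threshold).assign(
                    residue_index=s.residue_index, residue_name=s.residue_name
                )
                for s in state_series
            ]
        ).to_csv(summary_path, index=False, float_format="%.6f")
        manifest.record(
            "rotamers",
            {"chi": chi_path, "states": states_path, "summary": summary_path},
            t0,
        )

        # -- ecc -----------------------------------------------------------
        t0 = time.time()
        ecc_label = config.ecc_label or ensemble.labels[0]
        a, sub = assignments[ecc_label]
        lbl_mask = (chi_series[0].labels["label"] == ecc_label).to_numpy()
        rot_sub = [
            rotamers.RotamerStateSeries(
                residue_index=s.residue_index,
                residue_name=s.residue_name,
                states=s.states[lbl_mask],
                scheme=s.scheme,
            )
            for s in state_series
        ]
        results = ecc_mod.ecc_scan(a.assignments, rot_sub)
        ecc_path = os.path.join(config.outdir, "ecc.csv")
        ecc_mod.results_table(results).to_csv(ecc_path, index=False, float_format="%.6f")
        bfac_path = os.path.join(config.outdir, "ecc_bfactor.pdb")
        ecc_mod.ecc_to_bfactor(
            results, ensemble.topology, ensemble.replicas[0].coords[0], bfac_path
        )
        manifest.record("ecc", {"table": ecc_path, "bfactor_pdb": bfac_path}, t0)

        # -- dwells + conditional histograms -------------------------------
        t0 = time.time()
        if config.conditioning_residue is not None:
            cond_res = config.conditioning_residue
        else:
            cond_res = max(results, key=lambda r: r.ecc).residue_index
        cond_states = next(s for s in rot_sub if s.residue_index == cond_res)

        min_len = config.dwell_min_length
        if min_len is None:
            min_len = max(1, len(ensemble.replicas[0].coords) // 3)
        dwells = rotamers.dwell_segments(cond_states, min_len, config.dwell_dominance)
        dwell_path = os.path.join(config.outdir, "dwells.csv")
        pd.DataFrame(dwells, columns=["start", "end", "state"]).to_csv(
            dwell_path, index=False
        )

        cond = conditional.condition_histograms(
            sub,
            cond_states,
            bins=config.histogram_bins,
            oblique_angle=config.oblique_angle,
            minor_threshold=config.minor_threshold,
        )
        frac_path = os.path.join(config.outdir, "conditional_fractions.csv")
        pd.DataFrame(
            [
                {"state": s.state, "fraction": s.fraction, "minor": s.minor}
                for s in cond.per_state
            ]
        ).to_csv(frac_path, index=False, float_format="%.6f")
        grids_path = os.path.join(config.outdir, "conditional_hist.npz")
        np.savez(
            grids_path,
            edges_x=cond.edges_x,
            edges_y=cond.edges_y,
            total=cond.total_hist2d,
            **{f"state_{s.state}": s.hist2d for s in cond.per_state},
        )
        manifest.record(
            "conditional",
            {"dwells": dwell_path, "fractions": frac_path, "grids": grids_path},
            t0,
        )

        # -- contacts for the top cluster's medoid --------------------------
        t0 = time.time()
        med_rep, med_frame = a.medoids[0]
        rep_idx = next(
            i
            for i, r in enumerate(ensemble.replicas)
            if r.label == ecc_label and r.replica_id == med_rep
        )
        contacts = conditional.contact_shell(
            ensemble, rep_idx, med_frame, cond_res, config.contact_cutoff
        )
        contacts_path = os.path.join(config.outdir, "contacts.csv")
        contacts.to_csv(contacts_path, index=False, float_format="%.3f")
        manifest.record("contacts", {"table": contacts_path}, t0)

        # -- kinetics -------------------------------------------------------
        t0 = time.time()
        kcfg = dict(config.kinetics)
        # default mapping: competent population = share of frames outside
        # the dominant rotamer state of the conditioning residue
        pops = cond_states.populations
        p_comp = float(np.clip(1.0 - pops.max(), 0.01, 0.99))
        scheme_k = kin_mod.KineticScheme(
            populations=np.array([p_comp, 1.0 - p_comp]),
            competent=np.array([True, False]),
            k_on_star=kcfg.get("k_on_star", 1.0),
            k_off=kcfg.get("k_off", 0.1),
            exchange_rate=kcfg.get("exchange_rate", 100.0),
            ligand_concentration=kcfg.get("ligand_concentration", 1.0),
        )
        scan = np.linspace(0.05, 0.95, int(kcfg.get("scan_points", 19)))
        curve = kin_mod.fine_tuning_curve(
            scheme_k, scan, scenario=kcfg.get("scenario", "on_only")
        )
        curve_path = os.path.join(config.outdir, "kinetics_curve.csv")
        curve.to_csv(curve_path, index=False, float_format="%.6g")
        eff = kin_mod.effective_rates(scheme_k)
        summary_k_path = os.path.join(config.outdir, "kinetics_summary.json")
        with open(summary_k_path, "w") as fh:
            json.dump(
                {
                    "p_competent": p_comp,
                    "k_on_eff": eff.k_on_eff,
                    "k_off_eff": eff.k_off_eff,
                    "K_d": eff.k_d,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        manifest.record(
            "kinetics", {"curve": curve_path, "summary": summary_k_path}, t0
        )
    except PipelineError:
        manifest.finish("failed")
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        manifest.finish("failed")
        raise PipelineError("pipeline", "unexpected", str(exc)) from exc

    path = manifest.finish("ok")
    manifest.data["manifest_path"] = path
    return manifest.data
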