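"""End-to-end pipeline driver: simulate -> preprocess -> identify the motor
network by group spatial ICA -> three connectivity constructions ->
significance-thresholded adjacency -> multimodal connectomes -> degree and
severity statistics, with a reproducible run manifest.

The driver operates on a synthetic cohort by default (the study's raw scans
are not deposited); every stage is also usable on its own with ingested
NIfTI data through the module APIs and the command line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import connectome as cnx
from . import io as mio
from . import networks as nets
from . import preproc as pre
from . import stats as mst
from . import synthio

__all__ = ["PIPELINE_SCHEMA", "default_config", "run_pipeline", "RunManifest"]

log = logging.getLogger("metaconn")

_COHORT_KEYS = {f.name for f in dataclasses.fields(synthio.CohortConfig)}

PIPELINE_SCHEMA = {
    "cohort": _COHORT_KEYS,
    "preproc": {"keep_last", "normalize_fpet", "normalize_fmri", "static_window"},
    "networks": {
        "use_ica",
        "n_components",
        "z_threshold",
        "motor_z_threshold",
        "min_fraction",
        "template_rois",
    },
    "connectivity": {"alpha"},
    "connectome": {"reference", "unit_statistic"},
}

_DEFAULTS = {
    "cohort": {},  # synthio.CohortConfig defaults
    "preproc": {
        "keep_last": 30,
        "normalize_fpet": True,
        "normalize_fmri": False,
        "static_window": "retained",  # or "all"
    },
    "networks": {
        "use_ica": True,
        "n_components": 10,
        "z_threshold": 1.5,
        "motor_z_threshold": 1.0,
        "min_fraction": 0.1,
        "template_rois": None,  # default: the planted motor unit
    },
    "connectivity": {"alpha": 0.05},
    "connectome": {"reference": "positive", "unit_statistic": "sum"},
}


def default_config(overrides=None) -> dict:
    """Validated pipeline configuration (defaults merged with overrides).

    ``overrides`` may be a mapping or a YAML path; unknown sections or keys
    are rejected before any stage runs.
    """
    cfg = {k: dict(v) for k, v in _DEFAULTS.items()}
    if overrides is not None:
        user = mio.load_config(overrides, PIPELINE_SCHEMA)
        for section, vals in user.items():
            cfg[section].update(vals or {})
    return cfg


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seed, per-stage output hashes."""

    config: dict
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0
    results: dict = field(default_factory=dict)

    def add_stage(self, name: str, files: dict[str, str], **info) -> None:
        self.stages.append({"stage": name, "files": files, **info})

    def stage_hashes(self) -> dict[str, dict[str, str]]:
        return {s["stage"]: s["files"] for s in self.stages}

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
            "started": self.started,
            "finished": self.finished,
            "results": self.results,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_jsonable)

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _restrict_adjacency(adj: conn.Adjacency, roi_ids) -> conn.Adjacency:
    roi_ids = np.asarray(roi_ids)
    pos = {int(r): k for k, r in enumerate(adj.roi_ids)}
    idx = np.array([pos[int(r)] for r in roi_ids])
    return conn.Adjacency(
        a=adj.a[np.ix_(idx, idx)].copy(),
        alpha=adj.alpha,
        roi_ids=roi_ids,
        source=adj.source + "/network",
    )


def _preprocess_subject_fpet(cohort, sid, pcfg):
    """Retained, normalized fPET region series + static sum for one subject."""
    atlas = cohort.atlas
    counts = atlas.voxel_counts.to_numpy(dtype=float)
    if cohort.fpet_scans is not None:
        scan = pre.SubjectScan(
            cohort.fpet_scans[sid], "fpet", sid, brain_mask=atlas.brain_mask
        )
        scan = pre.retain_frames(scan, pcfg["keep_last"])
        if pcfg["normalize_fpet"]:
            scan = pre.global_mean_normalize(scan)
        series = pre.extract_roi_series(scan, atlas)
        if pcfg["static_window"] == "all":
            full = pre.SubjectScan(
                cohort.fpet_scans[sid], "fpet", sid, brain_mask=atlas.brain_mask
            )
            if pcfg["normalize_fpet"]:
                full = pre.global_mean_normalize(full)
            static_vals = pre.extract_roi_series(
                pre.SubjectScan(
                    pre.sum_frames(full)[..., None], "spet", sid, brain_mask=atlas.brain_mask
                ),
                atlas,
            ).values[:, 0]
        else:
            static_vals = series.values.sum(axis=1)
        return series, static_vals, scan
    series = pre.RoiSeries(cohort.fpet_roi[sid], atlas.roi_ids, "fpet", sid)
    series = pre.retain_frames_roi(series, pcfg["keep_last"])
    if pcfg["normalize_fpet"]:
        series = pre.roi_global_mean_normalize(series, counts)
    return series, series.values.sum(axis=1), None


def _identify_network(cohort, fpet_scans_norm, ncfg, seed) -> dict:
    """Find the motor network from the patient group's fPET ICA.

    The component is selected by spatial match against a template (by
    default the planted motor unit's voxel indicator), thresholded at the
    sensorimotor z threshold and parcellated against the atlas.
    """
    atlas = cohort.atlas
    template_rois = ncfg["template_rois"] or list(cohort.truth.motor_rois["PD"])
    if not ncfg["use_ica"] or fpet_scans_norm is None:
        return {
            "roi_ids": sorted(int(r) for r in template_rois),
            "method": "template (ICA disabled)",
            "component": None,
            "match_r": None,
        }
    data, _, mask = nets.concatenate_group(fpet_scans_norm)
    k = min(ncfg["n_components"], min(data.shape) - 1)
    maps = nets.group_spatial_ica(
        data, n_components=k, seed=seed, mask=mask, group="PD", modality="fpet"
    )
    template = np.isin(atlas.label_volume, template_rois)[mask].astype(float)
    rs = [float(np.corrcoef(m, template)[0, 1]) for m in maps.maps]
    comp = int(np.argmax(np.abs(rs)))
    netmask = nets.threshold_component(maps, comp, z=ncfg["motor_z_threshold"])
    rois = nets.parcellate_mask(netmask, atlas, ncfg["min_fraction"])
    if not rois:  # threshold emptied the mask; fall back to the template
        return {
            "roi_ids": sorted(int(r) for r in template_rois),
            "method": "template (empty ICA mask)",
            "component": comp,
            "match_r": rs[comp],
        }
    return {
        "roi_ids": rois,
        "method": "group spatial ICA",
        "component": comp,
        "match_r": rs[comp],
        "n_components": k,
    }


def run_pipeline(config: dict | None = None, outdir=None, seed: int = 0) -> RunManifest:
    """Execute the full analysis chain on a (synthetic) cohort.

    Returns a :class:`RunManifest`; key numbers live in ``manifest.results``
    and all artefacts are written under ``outdir`` when given.
    """
    cfg = default_config(config) if not _is_validated(config) else config
    outdir = Path(outdir) if outdir is not None else None
    manifest = RunManifest(config=cfg, seed=int(seed), version=_version())
    manifest.started = time.time()

    def _emit(stage, files: dict[str, Path], **info):
        hashes = {str(p.relative_to(outdir)): _sha256(p) for p in files.values()} if outdir else {}
        manifest.add_stage(stage, hashes, **info)
        log.info("stage %-12s %s", stage, info or "")

    # ----- stage 1: cohort ------------------------------------------------
    cohort_cfg = synthio.CohortConfig(**cfg["cohort"])  # partial overrides on defaults
    cohort = synthio.simulate_cohort(cohort_cfg, seed=seed)
    atlas = cohort.atlas
    files: dict[str, Path] = {}
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        files["atlas"] = mio.write_nifti(
            atlas.label_volume.astype(np.int16), None, outdir / "atlas.nii"
        )
        files["lut"] = mio.write_roi_table(atlas, outdir / "roi_table.tsv")
        cpath = outdir / "cohort.tsv"
        cohort.subject_table.to_csv(cpath, sep="\t", index=False)
        files["cohort"] = cpath
        tpath = outdir / "truth_manifest.json"
        tpath.write_text(cohort.manifest_json())
        files["truth"] = tpath
    _emit("simulate", files, n_subjects=len(cohort.subjects), n_rois=atlas.n_rois)

    # ----- stage 2: preprocessing ----------------------------------------
    pcfg = cfg["preproc"]
    fpet_series: dict[str, pre.RoiSeries] = {}
    fmri_series: dict[str, pre.RoiSeries] = {}
    static_rows: dict[str, dict[str, np.ndarray]] = {"PD": {}, "HC": {}}
    pd_scans_norm = [] if (cohort.fpet_scans is not None) else None
    for s in cohort.subjects:
        series, static_vals, scan_norm = _preprocess_subject_fpet(cohort, s.subject_id, pcfg)
        fpet_series[s.subject_id] = series
        static_rows[s.group][s.subject_id] = static_vals
        if pd_scans_norm is not None and s.group == "PD" and scan_norm is not None:
            pd_scans_norm.append(scan_norm)
        if cohort.fmri_scans is not None:
            fscan = pre.SubjectScan(
                cohort.fmri_scans[s.subject_id], "fmri", s.subject_id,
                brain_mask=atlas.brain_mask,
            )
            if pcfg["normalize_fmri"]:
                fscan = pre.global_mean_normalize(fscan)
            fmri_series[s.subject_id] = pre.extract_roi_series(fscan, atlas)
        else:
            fmri_series[s.subject_id] = pre.RoiSeries(
                cohort.fmri_roi[s.subject_id], atlas.roi_ids, "fmri", s.subject_id
            )
    frame_hi = cohort.config.fpet_frames
    window = (frame_hi - pcfg["keep_last"] + 1, frame_hi)
    static = {
        g: pre.StaticUptake(
            pd.DataFrame.from_dict(static_rows[g], orient="index").set_axis(
                pd.Index(atlas.roi_ids, name="roi_id"), axis=1
            ),
            source_frames=window if pcfg["static_window"] == "retained" else (1, frame_hi),
            group=g,
        )
        for g in ("PD", "HC")
    }
    _emit("preprocess", {}, keep_last=pcfg["keep_last"], static_window=pcfg["static_window"])

    # ----- stage 3: motor network identification --------------------------
    network = _identify_network(cohort, pd_scans_norm, cfg["networks"], seed)
    net_rois = np.asarray(network["roi_ids"])
    files = {}
    if outdir:
        npath = outdir / "network_rois.tsv"
        pd.DataFrame({"roi_id": net_rois}).to_csv(npath, sep="\t", index=False)
        files["network"] = npath
    _emit("network", files, **{k: v for k, v in network.items() if k != "roi_ids"})

    # ----- stage 4: connectivity + adjacency -------------------------------
    alpha = cfg["connectivity"]["alpha"]
    results: dict[tuple[str, str], conn.ConnectivityResult] = {}
    subject_results: dict[str, dict[str, conn.ConnectivityResult]] = {"fpet": {}, "fmri": {}}
    for g in ("PD", "HC"):
        members = [s.subject_id for s in cohort.group_subjects(g)]
        results[("spet", g)] = conn.static_covariance(static[g])
        for modality, series_map in (("fpet", fpet_series), ("fmri", fmri_series)):
            per_subject = []
            for sid in members:
                res = conn.subject_connectivity(series_map[sid])
                res.group = g
                subject_results[modality][sid] = res
                per_subject.append(res)
            results[(modality, g)] = conn.group_mean_connectivity(per_subject)
    adjacency = {
        key: conn.build_adjacency(res, alpha=alpha) for key, res in results.items()
    }
    files = {}
    if outdir:
        for (modality, g), res in results.items():
            p = mio.write_matrix_tsv(
                res.z,
                res.roi_ids,
                outdir / f"connectivity_{modality}_{g}_z.tsv",
                sidecar={"modality": modality, "level": res.level, "group": g,
                         "n_units": res.n_units, "alpha": alpha, "matrix": "fisher_z"},
            )
            files[f"z_{modality}_{g}"] = p
            p = mio.write_matrix_tsv(
                adjacency[(modality, g)].a,
                res.roi_ids,
                outdir / f"adjacency_{modality}_{g}.tsv",
                sidecar={"modality": modality, "group": g, "alpha": alpha,
                         "matrix": "signed_adjacency"},
            )
            files[f"adj_{modality}_{g}"] = p
    _emit("connectivity", files, alpha=alpha)

    # ----- stage 5: multimodal connectomes ---------------------------------
    ccfg = cfg["connectome"]
    pairs = (("spet", "fmri"), ("fpet", "fmri"), ("spet", "fpet"))
    connectomes: dict[tuple[str, str, str, str], cnx.MultimodalConnectome] = {}
    dice_table = []
    for g in ("PD", "HC"):
        for m1, m2 in pairs:
            whole = cnx.common_edges(
                adjacency[(m1, g)], adjacency[(m2, g)], reference=ccfg["reference"]
            )
            whole.group = g
            connectomes[(m1, m2, g, "whole")] = whole
            net = cnx.common_edges(
                _restrict_adjacency(adjacency[(m1, g)], net_rois),
                _restrict_adjacency(adjacency[(m2, g)], net_rois),
                reference=ccfg["reference"],
            )
            net.group = g
            connectomes[(m1, m2, g, "network")] = net
            dice_table.append(
                {"pair": f"{m1}-{m2}", "group": g, "dice_whole": whole.dice,
                 "dice_network": net.dice}
            )
    dice_df = pd.DataFrame(dice_table)
    files = {}
    if outdir:
        for (m1, m2, g, scope), cm in connectomes.items():
            p = mio.write_matrix_tsv(
                cm.tertiary,
                cm.roi_ids,
                outdir / f"tertiary_{m1}-{m2}_{g}_{scope}.tsv",
                sidecar={"modalities": [m1, m2], "group": g, "scope": scope,
                         "dice": cm.dice, "reference": cm.reference},
            )
            files[f"tertiary_{m1}-{m2}_{g}_{scope}"] = p
        dpath = outdir / "dice.tsv"
        dice_df.to_csv(dpath, sep="\t", index=False)
        files["dice"] = dpath
    _emit("connectome", files, reference=ccfg["reference"])

    # ----- stage 6: degree + group statistics ------------------------------
    unit_stats: dict[str, pd.DataFrame] = {}
    degree_tables = {}
    for m1, m2 in pairs:
        deg = {
            g: cnx.nodal_degree(connectomes[(m1, m2, g, "whole")], count_sign="all")
            for g in ("PD", "HC")
        }
        degree_tables[f"{m1}-{m2}"] = deg
        unit_stats[f"{m1}-{m2}"] = mst.unit_degree_comparison(
            deg["HC"], deg["PD"], atlas.roi_table, alpha=alpha
        )
    # motor-unit degree inside the identified network
    motor_unit = set(atlas.rois_of_unit("cortical_motor"))
    net_motor = sorted(motor_unit & set(int(r) for r in net_rois))
    network_motor_degree = {}
    for m1, m2 in pairs:
        network_motor_degree[f"{m1}-{m2}"] = {
            g: int(
                cnx.nodal_degree(connectomes[(m1, m2, g, "network")], count_sign="all")
                .values.loc[:, [r for r in net_rois if int(r) in motor_unit]]
                .to_numpy()
                .sum()
            )
            for g in ("PD", "HC")
        }

    # subject-level motor degree vs severity (patients)
    patients = [s for s in cohort.group_subjects("PD") if s.severity is not None]
    sev = np.array([s.severity for s in patients])
    subj_deg = pd.DataFrame(
        {
            s.subject_id: cnx.subject_nodal_degree(
                subject_results["fpet"][s.subject_id], net_rois, alpha=alpha
            ).values.iloc[0]
            for s in patients
        }
    ).T  # patients x network regions
    motor_cols = [c for c in subj_deg.columns if int(c) in motor_unit]
    severity_res = None
    if len(patients) >= 4 and motor_cols:
        total = subj_deg[motor_cols].sum(axis=1).to_numpy(dtype=float)
        if np.ptp(total) > 0 and np.ptp(sev) > 0:
            severity_res = mst.spearman_severity(total, sev)
    cross_modal = {
        f"{m1}-{m2}/{g}": mst.cross_modal_association(results[(m1, g)], results[(m2, g)])
        for m1, m2 in pairs
        for g in ("PD", "HC")
    }
    files = {}
    if outdir:
        spath = outdir / "unit_degree_stats.tsv"
        pd.concat(unit_stats, names=["pair"]).reset_index(0).to_csv(
            spath, sep="\t", index=False
        )
        files["unit_stats"] = spath
        sdpath = outdir / "subject_motor_degree.tsv"
        subj_deg.to_csv(sdpath, sep="\t")
        files["subject_degree"] = sdpath
        for pair in ("spet-fmri", "fpet-fmri"):
            m1, m2 = pair.split("-")
            cm = connectomes[(m1, m2, "PD", "whole")]
            node, edge = mio.export_brainnet(
                cm, degree_tables[pair]["PD"], atlas, outdir / f"brainnet_{pair}_PD"
            )
            files[f"brainnet_{pair}_node"] = node
            files[f"brainnet_{pair}_edge"] = edge
    _emit("statistics", files)

    manifest.results = {
        "network_rois": [int(r) for r in net_rois],
        "network_method": network["method"],
        "dice": dice_df,
        "unit_stats": {k: v for k, v in unit_stats.items()},
        "network_motor_degree": network_motor_degree,
        "severity_spearman": None
        if severity_res is None
        else {"rho": severity_res.statistic, "p": severity_res.p, "n": severity_res.n[0]},
        "cross_modal": {k: {"r": v[0], "slope": v[1], "intercept": v[2]}
                        for k, v in cross_modal.items()},
    }
    manifest.finished = time.time()
    if outdir:
        manifest.write(outdir / "run_manifest.json")
    return manifest


def _is_validated(config) -> bool:
    return isinstance(config, dict) and set(config) == set(_DEFAULTS) and all(
        isinstance(v, dict) for v in config.values()
    )


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("metaconn")
    except Exception:  # pragma: no cover
        return "unknown"
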