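"""File formats: NIfTI round-trips, square matrix TSV with JSON sidecars,
cohort/ROI tables, BrainNet Viewer node/edge export, and YAML configuration.

All tabular output is tab-delimited UTF-8 with '.' decimal; matrices carry a
roi_id header row and column so files are diff-able and self-describing.
Each matrix gets a JSON sidecar with enough metadata (modality, level,
parameters) to re-derive it.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .connectome import DegreeTable, MultimodalConnectome
from .synthio import ToyAtlas

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_roi_table",
    "write_roi_table",
    "export_brainnet",
    "load_config",
]


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI file; returns (data array, affine).

    Integer label volumes keep their integer dtype.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # corrupt header, truncated file, ...
        raise ValueError(f"could not read NIfTI file {path}: {exc}") from exc
    return data, img.affine


def write_nifti(data: np.ndarray, affine: np.ndarray | None, path) -> Path:
    """Write an array as NIfTI-1. Uncompressed .nii keeps hashes bit-stable."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(data, affine)
    nib.save(img, str(path))
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_matrix_tsv(
    matrix: np.ndarray, roi_ids, path, sidecar: dict | None = None
) -> Path:
    """Write a square ROI x ROI matrix as TSV with roi_id header row/column."""
    matrix = np.asarray(matrix)
    roi_ids = list(np.asarray(roi_ids).tolist())
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if matrix.shape[0] != len(roi_ids):
        raise ValueError("roi_ids length must match matrix size")
    if len(set(roi_ids)) != len(roi_ids):
        raise ValueError("roi_ids must be unique")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(matrix, index=roi_ids, columns=roi_ids)
    df.index.name = "roi_id"
    # %.17g round-trips float64 exactly; integers stay integers
    df.to_csv(path, sep="\t", float_format="%.17g")
    if sidecar is not None:
        _sidecar_path(path).write_text(
            json.dumps({"roi_ids": roi_ids, **sidecar}, indent=2, sort_keys=True)
        )
    return path


def read_matrix_tsv(path) -> tuple[np.ndarray, np.ndarray, dict | None]:
    """Read a matrix TSV written by :func:`write_matrix_tsv`.

    Returns (matrix, roi_ids, sidecar-or-None); validates squareness,
    header uniqueness and sidecar/header agreement.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    roi_ids = df.index.to_numpy()
    cols = np.asarray([type(roi_ids[0])(c) for c in df.columns])
    if len(roi_ids) != len(cols) or not np.array_equal(roi_ids, cols):
        raise ValueError(f"matrix in {path} is not square with matching headers")
    if len(np.unique(roi_ids)) != len(roi_ids):
        raise ValueError(f"duplicated roi_id in {path}")
    sidecar = None
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())
        if "roi_ids" in sidecar and list(sidecar["roi_ids"]) != list(roi_ids.tolist()):
            raise ValueError(f"sidecar roi_ids disagree with header in {path}")
    return df.to_numpy(), roi_ids, sidecar


def write_roi_table(atlas: ToyAtlas, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    atlas.roi_table.to_csv(path, sep="\t", index=False)
    return path


def read_roi_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"roi_id", "name", "unit"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI table {path} must have columns {sorted(required)}")
    return df


def export_brainnet(
    connectome: MultimodalConnectome,
    degrees: DegreeTable,
    atlas: ToyAtlas,
    out_prefix,
    affine: np.ndarray | None = None,
    min_size: float = 0.5,
) -> tuple[Path, Path]:
    """Write BrainNet Viewer `.node` and `.edge` files for a connectome.

    `.node` rows are ``x y z color size label`` with color = functional-unit
    index and size proportional to nodal degree (zero-degree regions get the
    documented minimum size ``min_size``).  `.edge` is the whitespace-
    delimited R x R tertiary matrix.
    """
    roi_ids = np.asarray(connectome.roi_ids)
    deg = degrees.values
    if degrees.by != "roi" or not np.array_equal(np.asarray(deg.columns), roi_ids):
        raise ValueError("degree table does not match the connectome's regions")
    cents = atlas.centroids(affine).loc[roi_ids]
    units = atlas.roi_table.set_index("roi_id").loc[roi_ids]
    unit_code = {u: k + 1 for k, u in enumerate(dict.fromkeys(units["unit"]))}
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    node_path = out_prefix.with_suffix(".node")
    edge_path = out_prefix.with_suffix(".edge")
    deg_row = deg.iloc[0]
    lines = []
    for rid in roi_ids:
        x, y, z = cents.loc[rid]
        size = float(deg_row[rid]) if deg_row[rid] > 0 else min_size
        lines.append(
            f"{x:.3f}\t{y:.3f}\t{z:.3f}\t{unit_code[units.loc[rid, 'unit']]}\t"
            f"{size:g}\t{units.loc[rid, 'name']}"
        )
    node_path.write_text("\n".join(lines) + "\n")
    np.savetxt(edge_path, connectome.tertiary, fmt="%d", delimiter="\t")
    return node_path, edge_path


def load_config(path_or_mapping, schema: dict) -> dict:
    """Load and validate a nested YAML config against an allowed-key schema.

    ``schema`` maps section name -> set of allowed keys (or None for scalar
    entries).  Unknown sections or keys are errors, not warnings: a typo'd
    parameter silently falling back to a default is worse than a failure.
    """
    if isinstance(path_or_mapping, (str, Path)):
        with open(path_or_mapping) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(path_or_mapping)
    unknown = set(cfg) - set(schema)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    for section, allowed in schema.items():
        if allowed is None or section not in cfg:
            continue
        if not isinstance(cfg[section], dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        bad = set(cfg[section]) - set(allowed)
        if bad:
            raise ValueError(f"unknown key(s) in section {section!r}: {sorted(bad)}")
    return cfg
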