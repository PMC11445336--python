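"""Frame retention, global-mean intensity normalization, static summation and
atlas-based region signal extraction.

The dynamic PET preprocessing chain is: keep the last 30 of 90 one-minute
frames (early frames carry little signal under constant infusion), divide
each retained frame by its own in-mask global mean (so every frame's mean is
exactly 1), then average voxels within each atlas region to obtain the
region x frame series.  The static image is the voxelwise sum over the
retained frames.  fMRI series pass through the same extraction but are not
globally normalized by default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthio import ToyAtlas

__all__ = [
    "SubjectScan",
    "RoiSeries",
    "StaticUptake",
    "retain_frames",
    "global_mean_normalize",
    "sum_frames",
    "extract_roi_series",
    "collect_static_uptake",
    "retain_frames_roi",
    "roi_global_mean_normalize",
]


@dataclass
class SubjectScan:
    """One subject's 4D scan (x, y, z, frames) with its brain mask."""

    data: np.ndarray
    modality: str  # "fpet" | "fmri"
    subject_id: str
    brain_mask: np.ndarray | None = None
    frame_duration_s: float = 60.0
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("scan data must be 4D (x, y, z, frames)")
        if self.data.shape[3] < 1:
            raise ValueError("scan must have at least one frame")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.data.shape[:3], dtype=bool)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must equal the scan's spatial shape")
        if not self.brain_mask.any():
            raise ValueError("brain mask must contain at least one voxel")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class RoiSeries:
    """Region x frame signal matrix; row order follows ``roi_ids``."""

    values: np.ndarray
    roi_ids: np.ndarray
    modality: str
    subject_id: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.roi_ids):
            raise ValueError("values must be (n_rois, n_frames) matching roi_ids")
        if np.isnan(self.values).any():
            raise ValueError("RoiSeries must not contain missing values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=pd.Index(self.roi_ids, name="roi_id"))
        df.columns = [f"frame_{k + 1}" for k in range(self.n_frames)]
        return df


@dataclass
class StaticUptake:
    """Subject x region summed-uptake table for one group."""

    values: pd.DataFrame  # index subject_id, columns roi_id
    source_frames: tuple[int, int]  # 1-based inclusive frame range summed
    group: str = ""

    def __post_init__(self) -> None:
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("synthetic summed uptake must be strictly positive")


def retain_frames(scan: SubjectScan, keep_last: int = 30) -> SubjectScan:
    """Keep only the final ``keep_last`` frames (order preserved)."""
    if keep_last > scan.n_frames:
        raise ValueError(
            f"keep_last={keep_last} exceeds available frames ({scan.n_frames})"
        )
    if keep_last < 1:
        raise ValueError("keep_last must be >= 1")
    return dataclasses.replace(scan, data=scan.data[..., scan.n_frames - keep_last :])


def global_mean_normalize(scan: SubjectScan) -> SubjectScan:
    """Divide each frame by its own in-mask mean.

    Postcondition: every frame's in-mask mean equals 1 (to numerical
    tolerance), which makes the operation idempotent.
    """
    flat = scan.data[scan.brain_mask]  # (n_mask_voxels, frames)
    means = flat.mean(axis=0)
    if np.any(means == 0):
        bad = np.nonzero(means == 0)[0]
        raise ValueError(f"zero in-mask mean in frame(s) {bad.tolist()}")
    return dataclasses.replace(scan, data=scan.data / means, normalized=True)


def sum_frames(scan: SubjectScan) -> np.ndarray:
    """Voxelwise sum over the scan's current frames (the 'static' image).

    Applied after :func:`retain_frames`, this sums the retained window only.
    """
    return scan.data.sum(axis=3)


def extract_roi_series(scan: SubjectScan, atlas: ToyAtlas | np.ndarray) -> RoiSeries:
    """Unweighted mean signal per atlas region and frame.

    ``atlas`` may be a :class:`~metaconn.synthio.ToyAtlas` or a bare 3D label
    volume (regions = all positive labels, ascending).
    """
    if isinstance(atlas, ToyAtlas):
        labels, roi_ids = atlas.label_volume, atlas.roi_ids
    else:
        labels = np.asarray(atlas)
        roi_ids = np.unique(labels[labels > 0])
    if labels.shape != scan.data.shape[:3]:
        raise ValueError(
            f"atlas shape {labels.shape} != scan spatial shape {scan.data.shape[:3]}"
        )
    present = set(np.unique(labels))
    values = np.empty((len(roi_ids), scan.n_frames))
    for k, rid in enumerate(roi_ids):
        if int(rid) not in present:
            raise ValueError(f"roi_id {rid} absent from label volume")
        values[k] = scan.data[labels == rid].mean(axis=0)
    return RoiSeries(
        values=values,
        roi_ids=np.asarray(roi_ids),
        modality=scan.modality,
        subject_id=scan.subject_id,
        normalized=scan.normalized,
    )


def collect_static_uptake(
    sums: dict[str, np.ndarray],
    atlas: ToyAtlas,
    source_frames: tuple[int, int],
    group: str = "",
) -> StaticUptake:
    """Assemble the group-level subject x region summed-uptake table.

    ``sums`` maps subject_id to a 3D static image (output of
    :func:`sum_frames`); regional values are unweighted voxel means.
    """
    rows = {}
    for sid, vol in sums.items():
        scan = SubjectScan(vol[..., None], modality="spet", subject_id=sid)
        rows[sid] = extract_roi_series(scan, atlas).values[:, 0]
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = pd.Index(atlas.roi_ids, name="roi_id")
    df.index.name = "subject_id"
    return StaticUptake(values=df, source_frames=source_frames, group=group)


# ---------------------------------------------------------------------------
# region-level fast path (identical maths on already-extracted series)
# ---------------------------------------------------------------------------


def retain_frames_roi(series: RoiSeries, keep_last: int = 30) -> RoiSeries:
    if keep_last > series.n_frames:
        raise ValueError(
            f"keep_last={keep_last} exceeds available frames ({series.n_frames})"
        )
    return dataclasses.replace(series, values=series.values[:, series.n_frames - keep_last :])


def roi_global_mean_normalize(series: RoiSeries, voxel_counts: np.ndarray) -> RoiSeries:
    """Global-mean normalization on region series.

    The in-mask global mean of a frame equals the voxel-count-weighted mean
    of the region means, so the operation is exactly the volume-level one.
    """
    w = np.asarray(voxel_counts, dtype=float)
    if w.shape != (series.values.shape[0],):
        raise ValueError("voxel_counts must have one entry per region")
    means = (w[:, None] * series.values).sum(axis=0) / w.sum()
    if np.any(means == 0):
        raise ValueError("zero global mean frame")
    return dataclasses.replace(series, values=series.values / means, normalized=True)
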