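"""Shared fixtures: small atlases, region-level cohorts and the helper that
runs the connectivity chain on already-extracted region series."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metaconn import connectivity as conn
from metaconn import synthio
from metaconn.preproc import (
    RoiSeries,
    StaticUptake,
    retain_frames_roi,
    roi_global_mean_normalize,
)

#: Fixed fixture seeds for every stochastic multi-seed check.
FIXTURE_SEEDS = (11, 12, 13, 14, 15)

DEFAULT_ROI_COHORT = {
    "n_pd": 12,
    "n_hc": 13,
    "n_rois": 30,
    "grid_shape": (12, 12, 12),
    "edge_strength": 0.7,
    "severity_noise_sd": 4.5,
    "volumes": False,
}


def make_roi_cohort(seed: int, **overrides) -> synthio.SyntheticCohort:
    cfg = dict(DEFAULT_ROI_COHORT)
    cfg.update(overrides)
    return synthio.simulate_cohort(cfg, seed=seed)


def group_connectivity(cohort: synthio.SyntheticCohort, group: str):
    """sPET/fPET/fMRI group results + per-subject fPET results for one group.

    Mirrors the pipeline's region-level path: retain the last 30 fPET
    frames, global-mean normalize, correlate; sum retained frames for the
    static construction; fMRI series enter unnormalized.
    """
    atlas = cohort.atlas
    counts = atlas.voxel_counts.to_numpy(dtype=float)
    fpet_subject, fmri_subject, static_rows = [], [], {}
    for s in cohort.group_subjects(group):
        ser = RoiSeries(cohort.fpet_roi[s.subject_id], atlas.roi_ids, "fpet", s.subject_id)
        ser = roi_global_mean_normalize(retain_frames_roi(ser, 30), counts)
        fpet_subject.append(conn.subject_connectivity(ser))
        static_rows[s.subject_id] = ser.values.sum(axis=1)
        fmri_subject.append(
            conn.subject_connectivity(
                RoiSeries(cohort.fmri_roi[s.subject_id], atlas.roi_ids, "fmri", s.subject_id)
            )
        )
    static = StaticUptake(
        pd.DataFrame.from_dict(static_rows, orient="index").set_axis(
            pd.Index(atlas.roi_ids, name="roi_id"), axis=1
        ),
        source_frames=(61, 90),
        group=group,
    )
    return {
        "spet": conn.static_covariance(static),
        "fpet": conn.group_mean_connectivity(fpet_subject),
        "fmri": conn.group_mean_connectivity(fmri_subject),
        "fpet_subject": fpet_subject,
    }


@pytest.fixture(scope="session")
def atlas30() -> synthio.ToyAtlas:
    return synthio.make_toy_atlas()


@pytest.fixture(scope="session")
def roi_cohort() -> synthio.SyntheticCohort:
    """Default study-sized cohort (12 PD / 13 HC, 30 regions), series only."""
    return make_roi_cohort(FIXTURE_SEEDS[0])


@pytest.fixture(scope="session")
def tiny_adjacency_pair():
    """Two 5-region adjacencies with |M1| = 4, |M2| = 6 and 3 common edges."""

    def build(edges, signs=None):
        a = np.zeros((5, 5), dtype=np.int8)
        for k, (i, j) in enumerate(edges):
            v = 1 if signs is None else signs[k]
            a[i, j] = a[j, i] = v
        return conn.Adjacency(a=a, alpha=0.05, roi_ids=np.arange(1, 6))

    adj1 = build([(0, 1), (0, 2), (1, 2), (3, 4)])
    adj2 = build([(0, 1), (0, 2), (1, 2), (0, 3), (1, 3), (2, 4)])
    return adj1, adj2
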