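"""Synthetic multimodal cohort generation with known ground-truth network structure.

This module builds a fully synthetic stand-in for a constant-infusion
[18F]FDG-fPET + resting-state fMRI cohort study: a toy label atlas, dynamic
PET volumes (slowly rising time-activity curves with network-structured
fluctuations), autocorrelated BOLD-like volumes, a cohort table with a
motor-severity score, and a ground-truth record of every planted edge.

Generative model
----------------
Planted connectivity is a linear latent-factor model with one shared factor
per *edge community* (a clique of regions within one functional unit).  For
region ``i`` belonging to communities ``C(i)`` the standardized fluctuation
signal of the region mean is

    y_i(t) = sum_{k in C(i)} lambda_{ik} f_k(t) + sigma_i eps_i(t)

with i.i.d. standard-normal factors ``f_k`` and idiosyncratic terms
``eps_i``.  Loadings are ``lambda_{ik} = sqrt(s_k)`` where ``s_k`` is the
community's target correlation; for motor communities ``s_k`` is further
scaled by the subject's coupling score ``c`` in ``[0, 1]``.  With
``sigma_i^2 = 1 - sum_k lambda_{ik}^2`` every ``y_i`` has unit variance and
two regions sharing exactly one community correlate at

    corr(y_i, y_j) = lambda_ik lambda_jk = s_k   (or s_k * c for motor edges),

so target correlations are computable in closed form.  Regions that load on
no community carry no fluctuation at all (``y_i = 0``), which makes the
zero-strength limit an exact noiseless baseline.  If a region's total
loading power exceeds 1 its loadings are rescaled to unit power (flagged in
the manifest); this cannot occur with the default one-community-per-region
layout.

The idiosyncratic term is delivered through two channels: a fraction
``roi_coherent_frac`` of its standard deviation is a region-coherent series
(``eps_i`` painted uniformly over the parcel) and the remainder is
spatially white voxel-level physiological noise whose region mean has
exactly the complementary variance.  Both channels produce the same region-
level correlations, but only the coherent part forms a low-rank spatial
source; keeping it small mimics real data, where a network's shared
fluctuation dominates any parcel-aligned idiosyncrasy, and lets group
spatial ICA recover the planted communities as single components.

Modalities
----------
fPET   voxel value = b_i * t + a_i * y_i(t) * [t in last ``n_active`` frames]
       + N(0, noise_sd) per voxel, with per-minute frame index t = 1..90.
       The accumulation rate ``b_i = beta_i * (1 + uptake_cv * u_i)`` varies
       across subjects through a *subject-level* latent ``u_i`` with the
       same community loading structure, so summed static uptake covaries
       across subjects along the planted edges (the sPET construction).
fMRI   voxel value = baseline + amp * AR1(y_i)(t) + N(0, noise_sd); factor
       and idiosyncratic streams are AR(1)-filtered with the same
       coefficient, which preserves the contemporaneous correlation while
       giving each series lag-1 autocorrelation equal to the coefficient.

Randomness is driven by ``numpy.random.default_rng([seed, subject_index,
stream_tag])`` so each subject (and each stream within a subject) is
individually reproducible from one master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

__all__ = [
    "UNITS",
    "ToyAtlas",
    "Community",
    "GroundTruth",
    "Subject",
    "SyntheticCohort",
    "CohortConfig",
    "make_toy_atlas",
    "make_ground_truth",
    "simulate_subject_fpet",
    "simulate_subject_fmri",
    "simulate_subject_fpet_roi",
    "simulate_subject_fmri_roi",
    "simulate_cohort",
]

#: Functional units a toy region can belong to (lobule-level grouping).
UNITS = (
    "cortical_motor",
    "subcortical",
    "cerebellar",
    "frontal",
    "parietal",
    "occipital",
    "temporal",
)

_MIN_ROI_VOXELS = 8
_MAX_LOADING_POWER = 1.0

# stream tags for the per-subject substream scheme
_STREAM_FPET = 0
_STREAM_FMRI = 1
_STREAM_UPTAKE = 2
_STREAM_ROI_NOISE = 3
_COHORT_STREAM = 10_007  # cohort-level draws (coupling, severity, baselines)


def _rng(seed, *key) -> np.random.Generator:
    """Deterministic substream: default_rng over [seed, *key]."""
    if isinstance(seed, (tuple, list)):
        ent = [int(s) for s in seed]
    else:
        ent = [int(seed)]
    return np.random.default_rng(ent + [int(k) for k in key])


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------


@dataclass
class ToyAtlas:
    """Toy integer label atlas: a 3D label volume plus a region lookup table.

    ``label_volume`` holds 0 for background and 1..R for regions;
    ``roi_table`` has columns ``roi_id``, ``name``, ``unit``.
    """

    label_volume: np.ndarray
    roi_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.label_volume.shape)

    @property
    def roi_ids(self) -> np.ndarray:
        return self.roi_table["roi_id"].to_numpy()

    @property
    def n_rois(self) -> int:
        return len(self.roi_table)

    @property
    def voxel_counts(self) -> pd.Series:
        ids, counts = np.unique(self.label_volume[self.label_volume > 0], return_counts=True)
        return pd.Series(counts, index=ids, name="voxels").reindex(self.roi_ids)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_volume > 0

    def rois_of_unit(self, unit: str) -> list[int]:
        return self.roi_table.loc[self.roi_table["unit"] == unit, "roi_id"].tolist()

    def centroids(self, affine: np.ndarray | None = None) -> pd.DataFrame:
        """Unweighted voxel-index centroid per region, mapped through ``affine``."""
        rows = []
        for rid in self.roi_ids:
            idx = np.argwhere(self.label_volume == rid)
            c = idx.mean(axis=0)
            if affine is not None:
                c = (affine @ np.append(c, 1.0))[:3]
            rows.append(c)
        return pd.DataFrame(rows, index=self.roi_ids, columns=["x", "y", "z"])

    def validate(self) -> None:
        ids = self.roi_table["roi_id"].to_numpy()
        if len(ids) == 0:
            raise ValueError("atlas must define at least one region")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("roi_ids must be unique")
        if (ids <= 0).any():
            raise ValueError("roi_ids must be strictly positive")
        present = set(np.unique(self.label_volume)) - {0}
        if present != set(int(i) for i in ids):
            raise ValueError("roi_table and label_volume must list the same region ids")
        bad = set(self.roi_table["unit"]) - set(UNITS)
        if bad:
            raise ValueError(f"unknown functional units: {sorted(bad)}")


def _default_unit_assignment(n_rois: int) -> dict[str, int]:
    base, rem = divmod(n_rois, len(UNITS))
    return {u: base + (1 if k < rem else 0) for k, u in enumerate(UNITS)}


def make_toy_atlas(
    n_rois: int = 30,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    unit_assignment: Mapping[str, int] | None = None,
) -> ToyAtlas:
    """Partition a voxel grid into ``n_rois`` contiguous parcels.

    Parcels are consecutive runs of the C-order flattened grid (contiguous
    blocks), each with at least 8 voxels.  The call is deterministic: no
    randomness is involved.

    Raises
    ------
    ValueError
        If the grid cannot host ``n_rois`` parcels of >= 8 voxels, or the
        unit assignment does not sum to ``n_rois``.
    """
    if n_rois < 2:
        raise ValueError("n_rois must be >= 2")
    n_vox = int(np.prod(grid_shape))
    if n_vox < n_rois * _MIN_ROI_VOXELS:
        raise ValueError(
            f"grid of {n_vox} voxels cannot host {n_rois} parcels of >= {_MIN_ROI_VOXELS} voxels"
        )
    if unit_assignment is None:
        unit_assignment = _default_unit_assignment(n_rois)
    if sum(unit_assignment.values()) != n_rois:
        raise ValueError("unit_assignment counts must sum to n_rois")
    bad = set(unit_assignment) - set(UNITS)
    if bad:
        raise ValueError(f"unknown functional units: {sorted(bad)}")

    labels = np.zeros(n_vox, dtype=np.int32)
    for rid, chunk in enumerate(np.array_split(np.arange(n_vox), n_rois), start=1):
        labels[chunk] = rid

    units: list[str] = []
    for u in UNITS:
        units.extend([u] * unit_assignment.get(u, 0))
    per_unit_counter: dict[str, int] = {}
    names = []
    for u in units:
        per_unit_counter[u] = per_unit_counter.get(u, 0) + 1
        names.append(f"{u}_{per_unit_counter[u]}")
    table = pd.DataFrame(
        {"roi_id": np.arange(1, n_rois + 1, dtype=int), "name": names, "unit": units}
    )
    return ToyAtlas(label_volume=labels.reshape(grid_shape), roi_table=table)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Community:
    """A clique of regions sharing one latent factor."""

    name: str
    roi_ids: tuple[int, ...]
    strength: float
    motor: bool = False


@dataclass
class Subject:
    subject_id: str
    group: str  # "PD" | "HC"
    index: int  # position in the cohort (drives the seed substream)
    coupling_score: float
    severity: float | None = None


@dataclass
class GroundTruth:
    """Planted network structure and per-subject couplings.

    ``group_adjacency`` maps group name to the signed ternary R x R matrix of
    planted edges (union of community cliques).  ``baseline_uptake`` is the
    atlas-level accumulation rate beta_i shared by all subjects.
    """

    communities: dict[str, tuple[Community, ...]]
    group_adjacency: dict[str, np.ndarray]
    edge_strength: float
    baseline_uptake: np.ndarray
    coupling_score: dict[str, float]
    severity: dict[str, float]
    motor_rois: dict[str, tuple[int, ...]]
    roi_ids: np.ndarray
    capped_rois: list[int] = field(default_factory=list)

    def edges(self, group: str) -> list[tuple[int, int]]:
        """Planted (i, j) roi-id pairs, i < j, for one group."""
        a = self.group_adjacency[group]
        out = []
        for p, q in zip(*np.nonzero(np.triu(a, 1))):
            out.append((int(self.roi_ids[p]), int(self.roi_ids[q])))
        return out


def _adjacency_from_communities(
    communities: Sequence[Community], roi_ids: np.ndarray
) -> np.ndarray:
    pos = {int(r): k for k, r in enumerate(roi_ids)}
    a = np.zeros((len(roi_ids), len(roi_ids)), dtype=np.int8)
    for com in communities:
        for i in com.roi_ids:
            for j in com.roi_ids:
                if i != j:
                    a[pos[i], pos[j]] = 1
    return a


def default_communities(
    atlas: ToyAtlas, edge_strength: float, null_effect: bool = False
) -> dict[str, tuple[Community, ...]]:
    """Planted community layout: shared within-unit cliques in both groups
    plus an extended cortical-motor clique in the patient group only.

    Controls keep a reduced 3-region motor community; patients get the full
    motor unit, which plants the excess of motor-motor edges.  With
    ``null_effect`` both groups receive the control layout (used for type-I
    error checks).
    """
    shared = tuple(
        Community(u, tuple(atlas.rois_of_unit(u)), edge_strength)
        for u in UNITS
        if u != "cortical_motor" and len(atlas.rois_of_unit(u)) >= 2
    )
    motor = atlas.rois_of_unit("cortical_motor")
    if len(motor) < 3:
        raise ValueError("need >= 3 cortical_motor regions to plant the group contrast")
    hc_size = 3 if len(motor) >= 4 else 2
    hc_motor = Community("motor", tuple(motor[:hc_size]), edge_strength, motor=True)
    pd_motor = Community("motor", tuple(motor), edge_strength, motor=True)
    return {
        "HC": shared + (hc_motor,),
        "PD": shared + (hc_motor if null_effect else pd_motor,),
    }


def make_ground_truth(
    atlas: ToyAtlas,
    subjects: Sequence[Subject],
    edge_strength: float = 0.7,
    null_effect: bool = False,
    seed: int = 0,
    communities: dict[str, tuple[Community, ...]] | None = None,
) -> GroundTruth:
    """Assemble the planted truth for a cohort.

    ``communities`` overrides the default layout (useful for planting a
    bespoke structure in tests).

    Baseline uptake rates beta_i ~ U(0.8, 1.2) are drawn from the
    cohort-level stream of ``seed`` and shared by all subjects.
    """
    if not (0.0 <= edge_strength <= 1.0):
        raise ValueError("edge_strength must be in [0, 1]")
    if communities is None:
        communities = default_communities(atlas, edge_strength, null_effect=null_effect)
    roi_ids = atlas.roi_ids
    adjacency = {
        g: _adjacency_from_communities(coms, roi_ids) for g, coms in communities.items()
    }
    rng = _rng(seed, _COHORT_STREAM, 0)
    beta = rng.uniform(0.8, 1.2, size=atlas.n_rois)
    motor_rois = {
        g: tuple(r for c in coms if c.motor for r in c.roi_ids)
        for g, coms in communities.items()
    }
    capped: set[int] = set()
    for g, coms in communities.items():
        pos = {int(r): k for k, r in enumerate(roi_ids)}
        power = np.zeros(len(roi_ids))
        for com in coms:
            for r in com.roi_ids:
                power[pos[r]] += com.strength
        capped |= {int(roi_ids[k]) for k in np.nonzero(power > _MAX_LOADING_POWER)[0]}
    return GroundTruth(
        communities=communities,
        group_adjacency=adjacency,
        edge_strength=edge_strength,
        baseline_uptake=beta,
        coupling_score={s.subject_id: s.coupling_score for s in subjects},
        severity={s.subject_id: s.severity for s in subjects if s.severity is not None},
        motor_rois=motor_rois,
        roi_ids=roi_ids,
        capped_rois=sorted(capped),
    )


def _loading_matrix(
    truth: GroundTruth, group: str, coupling: float
) -> tuple[np.ndarray, np.ndarray]:
    """Region x community loading matrix and idiosyncratic s.d. vector.

    Regions outside every community get sigma = 0 (no fluctuation), so the
    zero-strength limit degenerates to the pure deterministic signal.
    """
    coms = truth.communities[group]
    pos = {int(r): k for k, r in enumerate(truth.roi_ids)}
    lam = np.zeros((len(truth.roi_ids), len(coms)))
    for k, com in enumerate(coms):
        s = com.strength * (coupling if com.motor else 1.0)
        for r in com.roi_ids:
            lam[pos[r], k] = np.sqrt(s)
    power = (lam**2).sum(axis=1)
    over = power > _MAX_LOADING_POWER
    if over.any():
        lam[over] *= np.sqrt(_MAX_LOADING_POWER / power[over])[:, None]
        power = (lam**2).sum(axis=1)
    sigma = np.where(power > 0, np.sqrt(np.clip(1.0 - power, 0.0, None)), 0.0)
    return lam, sigma


def _resolve_subject(subject) -> tuple[str, str, int, float]:
    if isinstance(subject, Subject):
        return subject.subject_id, subject.group, subject.index, subject.coupling_score
    raise TypeError("subject must be a synthio.Subject")


def _fpet_parts(
    truth: GroundTruth,
    subject: Subject,
    n_frames: int,
    seed,
    fluct_amp: float,
    uptake_cv: float,
    roi_coherent_frac: float,
    n_active: int | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Coherent region x frame fPET signal plus the white-channel noise scale.

    Returns (signal, extra_sd, n_active): ``signal`` holds the accumulation
    ramp and the region-coherent fluctuation; ``extra_sd`` is the region-mean
    standard deviation of the spatially white idiosyncratic channel, active
    in the last ``n_active`` frames only.
    """
    sid, group, idx, coupling = _resolve_subject(subject)
    if group not in truth.group_adjacency:
        raise ValueError(f"unknown group {group!r}")
    R = len(truth.roi_ids)
    n_active = min(30, n_frames) if n_active is None else min(n_active, n_frames)
    t = np.arange(1, n_frames + 1, dtype=float)
    frac = roi_coherent_frac

    # subject-level uptake latent (drives the across-subject sPET covariance)
    lam_full, sig_full = _loading_matrix(truth, group, coupling=1.0)
    rng_u = _rng(seed, idx, _STREAM_UPTAKE)
    g = rng_u.standard_normal(lam_full.shape[1])
    zeta = rng_u.standard_normal(R)
    u = lam_full @ g + sig_full * zeta
    b = truth.baseline_uptake * (1.0 + uptake_cv * u)
    b = np.clip(b, 0.1 * truth.baseline_uptake, None)  # keep uptake positive

    # within-subject temporal fluctuations, injected only in the active window
    lam, sigma = _loading_matrix(truth, group, coupling)
    rng_f = _rng(seed, idx, _STREAM_FPET)
    f = rng_f.standard_normal((lam.shape[1], n_active))
    eps = rng_f.standard_normal((R, n_active))
    y = np.zeros((R, n_frames))
    y[:, n_frames - n_active :] = lam @ f + frac * sigma[:, None] * eps

    signal = np.outer(b, t) + fluct_amp * truth.baseline_uptake[:, None] * y
    extra_sd = fluct_amp * truth.baseline_uptake * sigma * np.sqrt(1.0 - frac**2)
    return signal, extra_sd, n_active


def _ar1(x: np.ndarray, phi: float, burn: int = 200) -> np.ndarray:
    """Row-wise stationary AR(1) filter with unit marginal variance."""
    if phi == 0.0:
        return x[..., burn:]
    innov = np.sqrt(1.0 - phi**2) * x
    return _sig.lfilter([1.0], [1.0, -phi], innov, axis=-1)[..., burn:]


def _fmri_parts(
    truth: GroundTruth,
    subject: Subject,
    n_frames: int,
    ar_coefficient: float,
    seed,
    amp: float,
    baseline: float,
    roi_coherent_frac: float,
    burn: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Coherent region x frame fMRI signal plus the white-channel noise scale."""
    sid, group, idx, coupling = _resolve_subject(subject)
    if group not in truth.group_adjacency:
        raise ValueError(f"unknown group {group!r}")
    if not (0.0 <= ar_coefficient < 1.0):
        raise ValueError("ar_coefficient must be in [0, 1)")
    R = len(truth.roi_ids)
    frac = roi_coherent_frac
    lam, sigma = _loading_matrix(truth, group, coupling)
    rng = _rng(seed, idx, _STREAM_FMRI)
    f = _ar1(rng.standard_normal((lam.shape[1], n_frames + burn)), ar_coefficient, burn)
    eps = _ar1(rng.standard_normal((R, n_frames + burn)), ar_coefficient, burn)
    y = lam @ f + frac * sigma[:, None] * eps
    signal = baseline + amp * y
    extra_sd = amp * sigma * np.sqrt(1.0 - frac**2)
    return signal, extra_sd


def _voxel_rows(atlas: ToyAtlas) -> tuple[np.ndarray, np.ndarray]:
    """Flattened voxel -> region-row index map (row -1 = background)."""
    labels = atlas.label_volume.reshape(-1)
    pos = {int(r): k for k, r in enumerate(atlas.roi_ids)}
    row = np.array([pos.get(int(l), -1) for l in labels])
    return row, row >= 0


def simulate_subject_fpet(
    atlas: ToyAtlas,
    truth: GroundTruth,
    subject: Subject,
    n_frames: int = 90,
    noise_sd: float = 0.5,
    seed: int = 0,
    fluct_amp: float = 2.0,
    uptake_cv: float = 0.1,
    roi_coherent_frac: float = 0.5,
) -> np.ndarray:
    """Simulate one subject's 4D constant-infusion PET scan.

    Voxel signal = regional accumulation ramp ``b_i * t`` plus the latent
    network fluctuation (last 30 frames only, region-coherent part and
    spatially white physiological part) plus i.i.d. Gaussian scanner noise;
    see the module docstring for the generative equations.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    signal, extra_sd, n_active = _fpet_parts(
        truth, subject, n_frames, seed, fluct_amp, uptake_cv, roi_coherent_frac
    )
    rng = _rng(seed, subject.index, _STREAM_FPET, 1)
    row, inside = _voxel_rows(atlas)
    vol = np.zeros((row.size, n_frames))
    vol[inside] = signal[row[inside]]
    counts = atlas.voxel_counts.to_numpy(dtype=float)
    voxel_extra = (extra_sd * np.sqrt(counts))[row[inside]]
    if np.any(voxel_extra > 0):
        vol[np.ix_(inside, np.arange(n_frames - n_active, n_frames))] += (
            rng.standard_normal((inside.sum(), n_active)) * voxel_extra[:, None]
        )
    if noise_sd > 0:
        vol += rng.normal(0.0, noise_sd, size=vol.shape)
    return vol.reshape(atlas.shape + (n_frames,))


def simulate_subject_fmri(
    atlas: ToyAtlas,
    truth: GroundTruth,
    subject: Subject,
    n_frames: int = 490,
    ar_coefficient: float = 0.4,
    noise_sd: float = 1.0,
    seed: int = 0,
    amp: float = 1.0,
    baseline: float = 100.0,
    roi_coherent_frac: float = 0.5,
) -> np.ndarray:
    """Simulate one subject's 4D BOLD-like scan (AR(1) network factors, no ramp).

    The spatially white physiological channel is AR(1)-filtered with the
    same coefficient so region series keep the nominal lag-1 autocorrelation.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    signal, extra_sd = _fmri_parts(
        truth, subject, n_frames, ar_coefficient, seed, amp, baseline, roi_coherent_frac
    )
    rng = _rng(seed, subject.index, _STREAM_FMRI, 1)
    row, inside = _voxel_rows(atlas)
    vol = np.zeros((row.size, n_frames))
    vol[inside] = signal[row[inside]]
    counts = atlas.voxel_counts.to_numpy(dtype=float)
    voxel_extra = (extra_sd * np.sqrt(counts))[row[inside]]
    hot = voxel_extra > 0
    if hot.any():
        burn = 100
        noise = _ar1(
            rng.standard_normal((int(hot.sum()), n_frames + burn)), ar_coefficient, burn
        )
        vol[np.nonzero(inside)[0][hot]] += noise * voxel_extra[hot, None]
    if noise_sd > 0:
        vol += rng.normal(0.0, noise_sd, size=vol.shape)
    return vol.reshape(atlas.shape + (n_frames,))


def _roi_noise(
    atlas: ToyAtlas, noise_sd: float, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Noise on region means emulating voxel-averaged extraction: sd / sqrt(n_vox)."""
    counts = atlas.voxel_counts.to_numpy(dtype=float)
    return rng.standard_normal((atlas.n_rois, n_frames)) * (noise_sd / np.sqrt(counts))[:, None]


def simulate_subject_fpet_roi(
    atlas: ToyAtlas,
    truth: GroundTruth,
    subject: Subject,
    n_frames: int = 90,
    noise_sd: float = 0.5,
    seed: int = 0,
    fluct_amp: float = 2.0,
    uptake_cv: float = 0.1,
    roi_coherent_frac: float = 0.5,
) -> np.ndarray:
    """Region x frame fPET series without materializing voxels.

    Distributionally equivalent to extracting region means from the volume
    path: the white physiological channel enters at its region-mean scale
    and scanner noise as Gaussian noise with s.d. noise_sd/sqrt(n_vox).
    """
    signal, extra_sd, n_active = _fpet_parts(
        truth, subject, n_frames, seed, fluct_amp, uptake_cv, roi_coherent_frac
    )
    rng = _rng(seed, subject.index, _STREAM_ROI_NOISE, _STREAM_FPET)
    if np.any(extra_sd > 0):
        signal[:, n_frames - n_active :] += (
            rng.standard_normal((atlas.n_rois, n_active)) * extra_sd[:, None]
        )
    if noise_sd > 0:
        signal += _roi_noise(atlas, noise_sd, n_frames, rng)
    return signal


def simulate_subject_fmri_roi(
    atlas: ToyAtlas,
    truth: GroundTruth,
    subject: Subject,
    n_frames: int = 490,
    ar_coefficient: float = 0.4,
    noise_sd: float = 1.0,
    seed: int = 0,
    amp: float = 1.0,
    baseline: float = 100.0,
    roi_coherent_frac: float = 0.5,
) -> np.ndarray:
    """Region x frame fMRI series without materializing voxels."""
    signal, extra_sd = _fmri_parts(
        truth, subject, n_frames, ar_coefficient, seed, amp, baseline, roi_coherent_frac
    )
    rng = _rng(seed, subject.index, _STREAM_ROI_NOISE, _STREAM_FMRI)
    if np.any(extra_sd > 0):
        burn = 100
        noise = _ar1(
            rng.standard_normal((atlas.n_rois, n_frames + burn)), ar_coefficient, burn
        )
        signal += noise * extra_sd[:, None]
    if noise_sd > 0:
        signal += _roi_noise(atlas, noise_sd, n_frames, rng)
    return signal


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort (defaults mirror the study)."""

    n_pd: int = 12
    n_hc: int = 13
    n_rois: int = 30
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    edge_strength: float = 0.7
    severity_noise_sd: float = 4.5
    fpet_frames: int = 90
    fmri_frames: int = 490
    ar_coefficient: float = 0.4
    fpet_noise_sd: float = 0.5
    fmri_noise_sd: float = 1.0
    fluct_amp: float = 2.0
    fmri_amp: float = 1.0
    uptake_cv: float = 0.1
    roi_coherent_frac: float = 0.5
    coupling_low: float = 0.3
    coupling_high: float = 1.0
    hc_coupling: float = 0.6
    severity_offset: float = 15.0
    severity_slope: float = 30.0
    null_effect: bool = False
    volumes: bool = True

    REQUIRED = (
        "n_pd",
        "n_hc",
        "n_rois",
        "grid_shape",
        "edge_strength",
        "severity_noise_sd",
    )

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
        missing = [k for k in cls.REQUIRED if k not in cfg]
        if missing:
            raise ValueError(f"cohort config missing required keys: {missing}")
        d = dict(cfg)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """A complete simulated cohort plus its ground-truth manifest."""

    atlas: ToyAtlas
    subjects: list[Subject]
    truth: GroundTruth
    config: CohortConfig
    seed: int
    fpet_scans: dict[str, np.ndarray] | None
    fmri_scans: dict[str, np.ndarray] | None
    fpet_roi: dict[str, np.ndarray]
    fmri_roi: dict[str, np.ndarray]

    @property
    def subject_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "coupling_score": [s.coupling_score for s in self.subjects],
                "severity": [s.severity for s in self.subjects],
            }
        )

    def group_subjects(self, group: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == group]

    def manifest(self) -> dict:
        """JSON-able record of the planted truth for test assertions."""
        return {
            "seed": int(self.seed),
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.config).items()
            },
            "n_rois": int(self.atlas.n_rois),
            "groups": {
                g: [s.subject_id for s in self.group_subjects(g)] for g in ("PD", "HC")
            },
            "coupling_score": {k: float(v) for k, v in self.truth.coupling_score.items()},
            "severity": {k: float(v) for k, v in self.truth.severity.items()},
            "planted_edges": {g: self.truth.edges(g) for g in ("PD", "HC")},
            "motor_rois": {g: list(self.truth.motor_rois[g]) for g in ("PD", "HC")},
            "capped_rois": list(self.truth.capped_rois),
            "baseline_uptake": [float(b) for b in self.truth.baseline_uptake],
        }

    def manifest_json(self) -> str:
        return json.dumps(self.manifest(), indent=2, sort_keys=True)


def simulate_cohort(
    config: CohortConfig | Mapping | None = None, seed: int = 0
) -> SyntheticCohort:
    """Generate a full synthetic cohort (default: 12 PD + 13 HC, 30 regions).

    Patients draw a coupling score c ~ U(coupling_low, coupling_high) that
    scales their motor-community edge strength; severity is the affine
    transform ``offset + slope * c`` plus Gaussian noise, hence strictly
    increasing in c before noise.  Controls use a fixed coupling and carry
    no severity.  Identical (config, seed) regenerate bit-identical data.
    """
    if config is None:
        config = CohortConfig()
    elif isinstance(config, Mapping):
        config = CohortConfig.from_mapping(config)

    atlas = make_toy_atlas(config.n_rois, config.grid_shape)
    rng = _rng(seed, _COHORT_STREAM, 1)

    subjects: list[Subject] = []
    for k in range(config.n_pd):
        c = float(rng.uniform(config.coupling_low, config.coupling_high))
        if config.null_effect:
            c = config.hc_coupling
        sev = config.severity_offset + config.severity_slope * c
        sev += float(rng.normal(0.0, config.severity_noise_sd))
        subjects.append(
            Subject(f"PD{k + 1:02d}", "PD", index=k, coupling_score=c, severity=max(sev, 0.0))
        )
    for k in range(config.n_hc):
        subjects.append(
            Subject(
                f"HC{k + 1:02d}",
                "HC",
                index=config.n_pd + k,
                coupling_score=config.hc_coupling,
            )
        )

    truth = make_ground_truth(
        atlas,
        subjects,
        edge_strength=config.edge_strength,
        null_effect=config.null_effect,
        seed=seed,
    )

    fpet_roi, fmri_roi = {}, {}
    fpet_scans: dict[str, np.ndarray] | None = {} if config.volumes else None
    fmri_scans: dict[str, np.ndarray] | None = {} if config.volumes else None
    for s in subjects:
        fpet_roi[s.subject_id] = simulate_subject_fpet_roi(
            atlas,
            truth,
            s,
            n_frames=config.fpet_frames,
            noise_sd=config.fpet_noise_sd,
            seed=seed,
            fluct_amp=config.fluct_amp,
            uptake_cv=config.uptake_cv,
            roi_coherent_frac=config.roi_coherent_frac,
        )
        fmri_roi[s.subject_id] = simulate_subject_fmri_roi(
            atlas,
            truth,
            s,
            n_frames=config.fmri_frames,
            ar_coefficient=config.ar_coefficient,
            noise_sd=config.fmri_noise_sd,
            seed=seed,
            amp=config.fmri_amp,
            roi_coherent_frac=config.roi_coherent_frac,
        )
        if config.volumes:
            fpet_scans[s.subject_id] = simulate_subject_fpet(
                atlas,
                truth,
                s,
                n_frames=config.fpet_frames,
                noise_sd=config.fpet_noise_sd,
                seed=seed,
                fluct_amp=config.fluct_amp,
                uptake_cv=config.uptake_cv,
            )
            fmri_scans[s.subject_id] = simulate_subject_fmri(
                atlas,
                truth,
                s,
                n_frames=config.fmri_frames,
                ar_coefficient=config.ar_coefficient,
                noise_sd=config.fmri_noise_sd,
                seed=seed,
                amp=config.fmri_amp,
            )

    return SyntheticCohort(
        atlas=atlas,
        subjects=subjects,
        truth=truth,
        config=config,
        seed=int(seed),
        fpet_scans=fpet_scans,
        fmri_scans=fmri_scans,
        fpet_roi=fpet_roi,
        fmri_roi=fmri_roi,
    )
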