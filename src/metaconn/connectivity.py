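"""Interregional connectivity: Pearson matrices, Fisher z, significance and
signed adjacency.

Three constructions are supported, mirroring the three ways connectivity is
measured in a combined static-PET / dynamic-PET / fMRI design:

* ``static_covariance`` — group-level metabolic covariance: correlation of
  summed regional uptake *across subjects* (sPET; only defined per group).
* ``subject_connectivity`` — within-subject correlation of region time
  series *across frames* (fPET: 30 metabolic frames; fMRI: 490 volumes).
* ``group_mean_connectivity`` — mean Fisher-z across subjects with a
  per-edge one-sample t test against zero, used to threshold group figures.

Edges with p below alpha are binarized into a signed ternary adjacency
(+1 significant positive, -1 significant negative, 0 otherwise).  No
edge-level multiple-comparison correction is applied; correction happens
downstream at the level of unit-degree group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preproc import RoiSeries, StaticUptake

__all__ = [
    "ConnectivityResult",
    "Adjacency",
    "fisher_z",
    "static_covariance",
    "subject_connectivity",
    "group_mean_connectivity",
    "build_adjacency",
    "restrict_result",
]

_R_CLIP = 1.0 - 1e-7


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher transform atanh(r) with r clipped to +/-(1 - 1e-7).

    Clipping keeps z finite for degenerate perfectly-correlated pairs
    (e.g. a duplicated region).
    """
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


@dataclass
class ConnectivityResult:
    """Correlation, Fisher-z and p matrices for one modality and level.

    The diagonal is excluded from all statistics: r and z diagonals are set
    to 0, the p diagonal to 1.  ``n_units`` is the number of subjects for
    group/static results and the number of frames for subject-level ones.
    ``flags`` marks entries whose value is a documented convention rather
    than an estimate (zero-variance regions, degenerate t tests).
    """

    r: np.ndarray
    z: np.ndarray
    p: np.ndarray
    modality: str  # "spet" | "fpet" | "fmri"
    level: str  # "subject" | "group"
    n_units: int
    roi_ids: np.ndarray
    subject_id: str = ""
    group: str = ""
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = np.zeros_like(self.r, dtype=bool)
        for name in ("r", "z", "p"):
            m = getattr(self, name)
            if m.shape != (len(self.roi_ids),) * 2:
                raise ValueError(f"{name} matrix shape does not match roi_ids")


def _corr_with_p(X: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson matrix over rows of X plus two-sided t-distribution p-values.

    Zero-variance rows are flagged; their edges get r = 0, p = 1.
    """
    sd = X.std(axis=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(X)
    r = np.nan_to_num(np.atleast_2d(r), nan=0.0)
    if degenerate.any():
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    rc = np.clip(r, -_R_CLIP, _R_CLIP)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rc * np.sqrt(df / (1.0 - rc**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    flags = np.zeros_like(r, dtype=bool)
    if degenerate.any():
        flags[degenerate, :] = True
        flags[:, degenerate] = True
        p[degenerate, :] = 1.0
        p[:, degenerate] = 1.0
    return r, p, flags


def _finalize(r, p, flags, **kw) -> ConnectivityResult:
    z = fisher_z(r)
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(z, 0.0)
    np.fill_diagonal(p, 1.0)
    np.fill_diagonal(flags, True)
    return ConnectivityResult(r=r, z=z, p=p, flags=flags, **kw)


def static_covariance(static: StaticUptake, modality: str = "spet") -> ConnectivityResult:
    """Across-subject correlation of summed regional uptake for one group.

    Significance uses the correlation t test with n_subjects - 2 degrees of
    freedom (there is no subject dimension left for a one-sample test).

    Raises
    ------
    ValueError
        If fewer than 4 subjects are available or a region has zero
        variance across subjects (flagging alone would silently distort the
        group matrix, so this is an error at this level).
    """
    X = static.values.to_numpy().T  # regions x subjects
    n = X.shape[1]
    if n < 4:
        raise ValueError("static covariance needs >= 4 subjects")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = np.asarray(static.values.columns)[sd == 0]
        raise ValueError(f"zero-variance region(s) across subjects: {bad.tolist()}")
    r, p, flags = _corr_with_p(X, df=n - 2)
    return _finalize(
        r,
        p,
        flags,
        modality=modality,
        level="group",
        n_units=n,
        roi_ids=np.asarray(static.values.columns),
        group=static.group,
    )


def subject_connectivity(series: RoiSeries) -> ConnectivityResult:
    """Within-subject Pearson correlation of region series over frames."""
    T = series.n_frames
    if T < 4:
        raise ValueError("subject connectivity needs >= 4 frames")
    r, p, flags = _corr_with_p(series.values, df=T - 2)
    return _finalize(
        r,
        p,
        flags,
        modality=series.modality,
        level="subject",
        n_units=T,
        roi_ids=series.roi_ids,
        subject_id=series.subject_id,
    )


def group_mean_connectivity(results: list[ConnectivityResult]) -> ConnectivityResult:
    """Mean Fisher-z across subjects with per-edge one-sample t against 0.

    Degenerate edges (zero variance across subjects) follow a documented
    convention: nonzero mean -> p = 0, zero mean -> p = 1, both flagged.
    """
    if len(results) < 3:
        raise ValueError("group mean connectivity needs >= 3 subjects")
    roi_ids = results[0].roi_ids
    for res in results[1:]:
        if not np.array_equal(res.roi_ids, roi_ids):
            raise ValueError("all subject results must share identical roi_ids")
    Z = np.stack([res.z for res in results])
    n = Z.shape[0]
    mean_z = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    flags = np.any([res.flags for res in results], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_z / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    zero_sd = sd == 0
    p[zero_sd & (mean_z != 0)] = 0.0
    p[zero_sd & (mean_z == 0)] = 1.0
    flags |= zero_sd
    r = np.tanh(mean_z)
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(mean_z, 0.0)
    np.fill_diagonal(p, 1.0)
    np.fill_diagonal(flags, True)
    return ConnectivityResult(
        r=r,
        z=mean_z,
        p=p,
        flags=flags,
        modality=results[0].modality,
        level="group",
        n_units=n,
        roi_ids=roi_ids,
        group=results[0].group,
    )


@dataclass
class Adjacency:
    """Signed ternary adjacency: +1 / -1 where p < alpha, else 0."""

    a: np.ndarray
    alpha: float
    roi_ids: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a)
        if self.a.shape != (len(self.roi_ids),) * 2:
            raise ValueError("adjacency shape does not match roi_ids")
        if not np.array_equal(self.a, self.a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(self.a, (-1, 0, 1)).all():
            raise ValueError("adjacency entries must be in {-1, 0, +1}")


def build_adjacency(
    result: ConnectivityResult, alpha: float = 0.05, sign_from: str = "r"
) -> Adjacency:
    """Binarize a connectivity result keeping only significant edges."""
    if sign_from not in ("r", "mean_z", "z"):
        raise ValueError("sign_from must be 'r' or 'mean_z'")
    eff = result.r if sign_from == "r" else result.z
    a = (np.sign(eff) * (result.p < alpha)).astype(np.int8)
    np.fill_diagonal(a, 0)
    return Adjacency(
        a=a,
        alpha=alpha,
        roi_ids=result.roi_ids,
        source=f"{result.modality}/{result.level}/{result.group or result.subject_id}",
    )


def restrict_result(result: ConnectivityResult, roi_ids) -> ConnectivityResult:
    """Slice a result down to a region subset (e.g. a derived network)."""
    roi_ids = np.asarray(roi_ids)
    missing = set(roi_ids.tolist()) - set(np.asarray(result.roi_ids).tolist())
    if missing:
        raise ValueError(f"roi_ids not in result: {sorted(missing)}")
    pos = {int(r): k for k, r in enumerate(result.roi_ids)}
    idx = np.array([pos[int(r)] for r in roi_ids])
    sub = np.ix_(idx, idx)
    return ConnectivityResult(
        r=result.r[sub].copy(),
        z=result.z[sub].copy(),
        p=result.p[sub].copy(),
        flags=result.flags[sub].copy(),
        modality=result.modality,
        level=result.level,
        n_units=result.n_units,
        roi_ids=roi_ids,
        subject_id=result.subject_id,
        group=result.group,
    )
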