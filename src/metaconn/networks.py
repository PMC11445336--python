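"""Group spatial ICA, component thresholding and network parcellation.

Subjects' normalized series are temporally concatenated per group and
decomposed by spatial ICA: the concatenated frames x voxels matrix is
PCA-whitened to the requested number of components in a single reduction
stage (exact Gram-matrix eigendecomposition on the smaller side), then
rotated by FastICA (deflation, logcosh contrast) with seeded restarts on
non-convergence.  Component maps are z-scored over in-mask voxels and
sign-fixed so spatial skewness is non-negative, removing the ICA sign
ambiguity deterministically.

A component map thresholded at z (one-sided, positive tail) yields a binary
network mask, which is parcellated against the atlas: regions whose in-mask
voxel fraction reaches ``min_fraction`` form the network's region set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .preproc import RoiSeries, SubjectScan
from .synthio import ToyAtlas

__all__ = [
    "ComponentMaps",
    "NetworkMask",
    "concatenate_group",
    "group_spatial_ica",
    "threshold_component",
    "parcellate_mask",
    "match_components",
]


@dataclass
class ComponentMaps:
    """Spatial ICA result: z-scored component maps over in-mask voxels.

    ``maps`` is components x voxels (in-mask order); ``mixing`` is the
    frames x components back-projection of the concatenated data onto the
    maps.  ``mask`` (optional 3D boolean) records the voxel space so maps
    can be unflattened.
    """

    maps: np.ndarray
    n_components: int
    mixing: np.ndarray
    seed: int
    group: str = ""
    modality: str = ""
    mask: np.ndarray | None = None
    converged: bool = True
    restarts_used: int = 0

    def map_volume(self, component: int) -> np.ndarray:
        if self.mask is None:
            raise ValueError("no voxel mask attached")
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.maps[component]
        return vol


@dataclass
class NetworkMask:
    """Binary network mask from one thresholded component."""

    mask: np.ndarray  # boolean; 3D when a voxel mask was attached, else flat
    threshold_z: float
    source_component: int
    roi_ids: list[int] | None = None


def concatenate_group(
    series_list, demean: bool = True
) -> tuple[np.ndarray, list[int], np.ndarray | None]:
    """Temporally concatenate subjects' series for group ICA.

    Accepts 4D :class:`SubjectScan` objects (in-mask voxels become columns),
    :class:`RoiSeries` (regions as columns) or bare frames x voxels arrays.
    Returns (frames_total x voxels matrix, per-subject frame offsets, shared
    3D mask or None).

    With ``demean`` (default) each subject's voxelwise temporal mean is
    removed before stacking.  Without it, every subject's static uptake map
    enters the decomposition as a constant-in-time spatial direction and
    crowds out the temporal fluctuation networks the ICA is after.
    """
    if not series_list:
        raise ValueError("need at least one subject")
    blocks, mask = [], None
    for item in series_list:
        if isinstance(item, SubjectScan):
            if mask is None:
                mask = item.brain_mask
            elif not np.array_equal(mask, item.brain_mask):
                raise ValueError("all scans must share the same mask")
            blocks.append(item.data[mask].T)  # frames x voxels
        elif isinstance(item, RoiSeries):
            blocks.append(item.values.T)
        else:
            blocks.append(np.asarray(item, dtype=float))
    width = blocks[0].shape[1]
    for b in blocks:
        if b.shape[1] != width:
            raise ValueError("all subjects must share the same voxel/region count")
    if demean:
        blocks = [b - b.mean(axis=0, keepdims=True) for b in blocks]
    offsets = list(np.cumsum([0] + [b.shape[0] for b in blocks[:-1]]))
    return np.vstack(blocks), offsets, mask


def _whiten_spatial(data: np.ndarray, k: int) -> np.ndarray:
    """Exact single-stage PCA whitening of the spatial (voxel-sample) view.

    Returns voxels x k scores with identity covariance over voxels, using
    the Gram matrix of whichever side of the frames x voxels matrix is
    smaller.
    """
    F, V = data.shape
    Xc = data - data.mean(axis=1, keepdims=True)  # zero-mean over voxels per frame
    if F <= V:
        G = Xc @ Xc.T
        vals, U = np.linalg.eigh(G)
        order = np.argsort(vals)[::-1][:k]
        vals, U = vals[order], U[:, order]
        if np.any(vals <= 1e-12 * vals.max()):
            raise ValueError("data rank below requested number of components")
        Vt = (U / np.sqrt(vals)).T @ Xc  # k x V, orthonormal rows
    else:
        C = Xc.T @ Xc
        vals, W = np.linalg.eigh(C)
        order = np.argsort(vals)[::-1][:k]
        vals, W = vals[order], W[:, order]
        if np.any(vals <= 1e-12 * vals.max()):
            raise ValueError("data rank below requested number of components")
        Vt = W.T  # k x V
    return np.sqrt(V) * Vt.T  # voxels x k, unit variance per column


def group_spatial_ica(
    data: np.ndarray,
    n_components: int = 10,
    seed: int = 0,
    mask: np.ndarray | None = None,
    max_restarts: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-6,
    group: str = "",
    modality: str = "",
) -> ComponentMaps:
    """Spatial ICA of a concatenated frames x voxels matrix.

    Raises
    ------
    ValueError
        If ``n_components`` exceeds min(frames, voxels).
    RuntimeError
        If FastICA fails to converge after ``max_restarts`` seeded restarts.
    """
    data = np.asarray(data, dtype=float)
    F, V = data.shape
    if n_components > min(F, V):
        raise ValueError("n_components must be <= min(frames_total, voxels)")
    Z = _whiten_spatial(data, n_components)  # voxels x k
    sources = None
    restarts = 0
    for attempt in range(max_restarts):
        rs = int(np.random.default_rng([int(seed), attempt]).integers(2**31 - 1))
        ica = FastICA(
            n_components=n_components,
            whiten=False,
            algorithm="deflation",
            fun="logcosh",
            max_iter=max_iter,
            tol=tol,
            random_state=rs,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            S = ica.fit_transform(Z)
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            sources = S
            restarts = attempt
            break
    if sources is None:
        raise RuntimeError(
            f"FastICA did not converge after {max_restarts} seeded restarts"
        )
    maps = sources.T  # k x voxels
    maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
    flip = sps.skew(maps, axis=1) < 0
    maps[flip] *= -1.0
    # mixing: least-squares back-projection of the (voxel-centered) data
    Xc = data - data.mean(axis=1, keepdims=True)
    mixing = Xc @ np.linalg.pinv(maps)
    return ComponentMaps(
        maps=maps,
        n_components=n_components,
        mixing=mixing,
        seed=int(seed),
        group=group,
        modality=modality,
        mask=mask,
        converged=True,
        restarts_used=restarts,
    )


def threshold_component(
    maps: ComponentMaps, component: int, z: float = 1.5
) -> NetworkMask:
    """Binary mask of voxels whose map value exceeds z (positive tail).

    The default threshold is 1.5; a lower threshold (1.0) is used for the
    sensorimotor component so all cortical clusters survive.
    """
    if not (0 <= component < maps.n_components):
        raise ValueError(f"component {component} out of range [0, {maps.n_components})")
    flat = maps.maps[component] > z
    if maps.mask is not None:
        vol = np.zeros(maps.mask.shape, dtype=bool)
        vol[maps.mask] = flat
        return NetworkMask(mask=vol, threshold_z=z, source_component=component)
    return NetworkMask(mask=flat, threshold_z=z, source_component=component)


def parcellate_mask(
    mask: NetworkMask | np.ndarray, atlas: ToyAtlas, min_fraction: float = 0.1
) -> list[int]:
    """Regions whose in-mask voxel fraction reaches ``min_fraction``.

    With ``min_fraction = 0`` every region overlapping at least one voxel is
    returned.  Output is sorted by roi_id; an empty list is allowed.
    """
    if not (0.0 <= min_fraction <= 1.0):
        raise ValueError("min_fraction must be in [0, 1]")
    m = mask.mask if isinstance(mask, NetworkMask) else np.asarray(mask, dtype=bool)
    if m.shape != atlas.shape:
        raise ValueError("mask shape must equal atlas shape")
    out = []
    for rid in atlas.roi_ids:
        inside = atlas.label_volume == rid
        frac = m[inside].mean()
        if (frac >= min_fraction and frac > 0) or (min_fraction == 0 and m[inside].any()):
            out.append(int(rid))
    return sorted(out)


def match_components(
    maps_a: ComponentMaps, maps_b: ComponentMaps
) -> list[tuple[int, int, float]]:
    """One-to-one component pairing maximizing total |spatial correlation|.

    Uses the optimal (Hungarian) assignment over the |r| matrix; each pair
    is reported with its signed spatial correlation.
    """
    A, B = maps_a.maps, maps_b.maps
    if A.shape[1] != B.shape[1]:
        raise ValueError("component maps must share the same voxel count")
    ka, kb = A.shape[0], B.shape[0]
    corr = np.empty((ka, kb))
    for i in range(ka):
        for j in range(kb):
            corr[i, j] = np.corrcoef(A[i], B[j])[0, 1]
    rows, cols = linear_sum_assignment(-np.abs(corr))
    return [(int(i), int(j), float(corr[i, j])) for i, j in zip(rows, cols)]
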