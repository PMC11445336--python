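"""Multimodal common-edge connectomes, Sörensen–Dice similarity and nodal
degree.

Two modality-specific adjacencies are intersected edge-wise: an edge is
*common* iff it is significant in both modalities with the same sign.  The
resulting tertiary matrix keeps the shared sign (+1 common positive, -1
common negative).  Cross-modal correspondence is quantified by the
Sörensen–Dice coefficient

    DC = 2 |M1 ∩ M2| / (|M1| + |M2|)

over upper-triangle edge sets, by default restricted to positive edges.
Nodal degree is the number of counted edges incident to a region, optionally
aggregated per functional unit (lobule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import Adjacency, ConnectivityResult

__all__ = [
    "MultimodalConnectome",
    "DegreeTable",
    "common_edges",
    "dice",
    "nodal_degree",
    "aggregate_by_unit",
    "subject_nodal_degree",
]


@dataclass
class MultimodalConnectome:
    """Common-edge (tertiary) matrix of two adjacencies plus its Dice value."""

    tertiary: np.ndarray
    dice: float
    modalities: tuple[str, str]
    roi_ids: np.ndarray
    reference: str = "positive"
    group: str = ""
    dice_degenerate: bool = False  # both edge sets empty (0/0 convention -> 0)


@dataclass
class DegreeTable:
    """Degree values, one column per region (or unit), one row per observation.

    Group-level tables have a single row; subject-level tables one row per
    subject.  ``by`` records whether columns are regions or functional units.
    """

    values: pd.DataFrame
    level: str  # "group" | "subject"
    by: str = "roi"  # "roi" | "unit"
    count_sign: str = "all"


def _check_same_rois(a: Adjacency, b: Adjacency) -> None:
    if not np.array_equal(np.asarray(a.roi_ids), np.asarray(b.roi_ids)):
        raise ValueError("adjacencies must share identical roi_ids")


def _edge_mask(a: np.ndarray, reference: str) -> np.ndarray:
    u = np.triu(a, 1)
    if reference == "positive":
        return u == 1
    if reference == "all":
        return u != 0
    raise ValueError("reference must be 'positive' or 'all'")


def dice(adj1: Adjacency, adj2: Adjacency, reference: str = "positive") -> float:
    """Sörensen–Dice coefficient of two edge sets (upper triangle).

    Common edges must agree in sign.  Returns 0 when both sets are empty
    (the formula is 0/0 there).
    """
    _check_same_rois(adj1, adj2)
    m1 = _edge_mask(adj1.a, reference)
    m2 = _edge_mask(adj2.a, reference)
    common = m1 & m2 & (np.triu(adj1.a, 1) == np.triu(adj2.a, 1))
    denom = int(m1.sum()) + int(m2.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int(common.sum()) / denom


def common_edges(
    adj1: Adjacency, adj2: Adjacency, reference: str = "positive"
) -> MultimodalConnectome:
    """Edge-wise intersection of two adjacencies with sign agreement.

    The tertiary matrix keeps every sign-consistent common edge regardless
    of ``reference``; the reference only restricts the Dice counting.
    """
    _check_same_rois(adj1, adj2)
    same_sign = (adj1.a == adj2.a) & (adj1.a != 0)
    tertiary = np.where(same_sign, adj1.a, 0).astype(np.int8)
    m1 = _edge_mask(adj1.a, reference)
    m2 = _edge_mask(adj2.a, reference)
    dc = dice(adj1, adj2, reference)
    degenerate = int(m1.sum()) + int(m2.sum()) == 0
    mod1 = adj1.source.split("/")[0] if adj1.source else "m1"
    mod2 = adj2.source.split("/")[0] if adj2.source else "m2"
    return MultimodalConnectome(
        tertiary=tertiary,
        dice=dc,
        modalities=(mod1, mod2),
        roi_ids=np.asarray(adj1.roi_ids),
        reference=reference,
        group=getattr(adj1, "group", ""),
        dice_degenerate=degenerate,
    )


def nodal_degree(
    m: Adjacency | MultimodalConnectome | np.ndarray,
    count_sign: str = "all",
    roi_ids=None,
    level: str = "group",
) -> DegreeTable:
    """Number of counted nonzero off-diagonal entries per row."""
    if isinstance(m, Adjacency):
        mat, ids = m.a, m.roi_ids
    elif isinstance(m, MultimodalConnectome):
        mat, ids = m.tertiary, m.roi_ids
    else:
        mat = np.asarray(m)
        ids = np.arange(1, mat.shape[0] + 1) if roi_ids is None else np.asarray(roi_ids)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("input must be square")
    if not np.array_equal(mat, mat.T):
        raise ValueError("input must be symmetric")
    work = mat.copy()
    np.fill_diagonal(work, 0)
    if count_sign == "positive":
        counted = work == 1
    elif count_sign == "all":
        counted = work != 0
    else:
        raise ValueError("count_sign must be 'positive' or 'all'")
    deg = counted.sum(axis=1).astype(int)
    df = pd.DataFrame([deg], columns=pd.Index(ids, name="roi_id"), index=["degree"])
    return DegreeTable(values=df, level=level, by="roi", count_sign=count_sign)


def aggregate_by_unit(
    degrees: DegreeTable, roi_table: pd.DataFrame, statistic: str = "sum"
) -> DegreeTable:
    """Aggregate region degrees per functional unit (sum or mean of members)."""
    if degrees.by != "roi":
        raise ValueError("degrees must be per region")
    if statistic not in ("sum", "mean"):
        raise ValueError("statistic must be 'sum' or 'mean'")
    mapping = roi_table.set_index("roi_id")["unit"]
    cols = degrees.values.columns
    unmapped = [c for c in cols if c not in mapping.index]
    if unmapped:
        raise ValueError(f"regions with no unit mapping: {unmapped}")
    grouped = degrees.values.T.groupby(mapping.loc[cols].to_numpy())
    agg = grouped.sum().T if statistic == "sum" else grouped.mean().T
    agg.columns.name = "unit"
    return DegreeTable(
        values=agg, level=degrees.level, by="unit", count_sign=degrees.count_sign
    )


def subject_nodal_degree(
    result: ConnectivityResult, network_rois, alpha: float = 0.05
) -> DegreeTable:
    """Per-region count of significant within-network edges for one subject."""
    network_rois = np.asarray(network_rois)
    all_ids = np.asarray(result.roi_ids)
    missing = set(network_rois.tolist()) - set(all_ids.tolist())
    if missing:
        raise ValueError(f"network regions outside the parcellation: {sorted(missing)}")
    pos = {int(r): k for k, r in enumerate(all_ids)}
    idx = np.array([pos[int(r)] for r in network_rois])
    sub_p = result.p[np.ix_(idx, idx)]
    sig = sub_p < alpha
    np.fill_diagonal(sig, False)
    deg = sig.sum(axis=1).astype(int)
    df = pd.DataFrame(
        [deg],
        columns=pd.Index(network_rois, name="roi_id"),
        index=[result.subject_id or "subject"],
    )
    return DegreeTable(values=df, level="subject", by="roi", count_sign="all")
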