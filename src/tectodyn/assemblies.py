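"""Recurring coactive neuron groups and their spatial / tuning statistics.

Assemblies are detected per epoch from the binary raster: the baseline
detector builds the graph of SHIFT-significant positively correlated neuron
pairs and partitions it with modularity-maximising community detection
(pluggable, so a dedicated assembly-detection algorithm can be substituted).
Statistics follow the tectal conventions: centre of mass projected onto the
anterior-posterior axis (major axis of an ellipse fitted to the neuropil
contour), convex-hull spatial coverage, and tuning mean/variance over the
assembly's selective members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import EllipseModel

from . import correlations
from .preprocessing import BinaryRaster

__all__ = [
    "Assembly",
    "ApAxis",
    "fit_ap_axis",
    "detect_assemblies",
    "assembly_statistics",
    "assembly_overlap",
    "assembly_table",
]

DEFAULT_MIN_SIZE = 5


@dataclass
class ApAxis:
    """Anterior-posterior axis from the neuropil ellipse fit.

    ``unit`` points from anterior (projection 0) to posterior (projection 1);
    the projection maps the major-axis span [-a, a] around the centre onto
    [0, 1].
    """

    center: np.ndarray
    semi_major: float
    semi_minor: float
    angle_rad: float
    unit: np.ndarray

    def project(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        t = (pts - self.center) @ self.unit / (2.0 * self.semi_major) + 0.5
        return t if t.size > 1 else float(t[0])


@dataclass
class Assembly:
    """A recurring group of coactive neurons with summary statistics."""

    members: np.ndarray
    epoch: str
    com_xy: Optional[np.ndarray] = None
    com_ap: float = np.nan
    coverage: float = np.nan
    mean_tuning_deg: float = np.nan
    tuning_variance_deg2: float = np.nan

    def __post_init__(self) -> None:
        self.members = np.sort(np.asarray(self.members, dtype=int))

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# AP axis
# ---------------------------------------------------------------------------


def fit_ap_axis(neuropil_contour: np.ndarray) -> ApAxis:
    """Least-squares ellipse fit to the neuropil contour.

    The major axis defines the anterior-posterior axis; the anterior end is
    the major-axis endpoint nearer the coordinate origin (a convention —
    polarity cannot be inferred from geometry alone).
    """
    pts = np.asarray(neuropil_contour, dtype=float)
    if pts.shape[0] < 6:
        raise ValueError("need at least 6 contour points")
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-8) < 2:
        raise ValueError("contour points are collinear; ellipse fit is degenerate")
    try:  # scikit-image >= 0.26
        model = EllipseModel.from_estimate(pts)
        if not model:
            raise ValueError("ellipse fit failed")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    except AttributeError:
        model = EllipseModel()
        if not model.estimate(pts):
            raise ValueError("ellipse fit failed")
        xc, yc, a, b, theta = model.params
    if b > a:
        a, b = b, a
        theta += math.pi / 2.0
    theta = theta % math.pi
    u = np.array([math.cos(theta), math.sin(theta)])
    center = np.array([xc, yc])
    e0, e1 = center - a * u, center + a * u
    if np.linalg.norm(e0) > np.linalg.norm(e1):
        u = -u
    return ApAxis(center=center, semi_major=float(a), semi_minor=float(b),
                  angle_rad=float(theta), unit=u)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _graph_community_detector(
    r: np.ndarray, mask: np.ndarray, min_size: int, seed: Optional[int]
) -> List[np.ndarray]:
    """Baseline detector: modularity communities of the significance graph."""
    edges = np.argwhere(np.triu(mask, k=1))
    if len(edges) == 0:
        return []
    g = nx.Graph()
    for i, j in edges:
        g.add_edge(int(i), int(j), weight=max(float(r[i, j]), 1e-6))
    comms = nx.algorithms.community.greedy_modularity_communities(g, weight="weight")
    out = [np.sort(np.fromiter(c, dtype=int)) for c in comms if len(c) >= min_size]
    out.sort(key=lambda m: (int(m[0]), -len(m)))
    return out


def detect_assemblies(
    raster: BinaryRaster,
    epoch_frames: Sequence[int],
    epoch: str = "SA",
    detector: Union[str, Callable] = "graph-community",
    min_size: int = DEFAULT_MIN_SIZE,
    n_shuffles: int = 500,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> List[Assembly]:
    """Detect recurring coactive groups on the epoch-restricted raster.

    A ``detector`` callable receives ``(r, mask, min_size, seed)`` and returns
    membership arrays, so the full graph-theoretic algorithm of choice can be
    plugged in; the default partitions the SHIFT-significance graph by
    greedy modularity maximisation.  Communities smaller than ``min_size``
    are discarded; an empty significance graph yields zero assemblies.
    """
    frames = np.asarray(epoch_frames)
    if len(frames) < 50:
        raise ValueError("epoch must contain at least 50 frames for detection")
    result = correlations.shift_null_mask(
        raster.B.astype(float), frames, n_shuffles=n_shuffles, seed=seed, alpha=alpha
    )
    if callable(detector):
        memberships = detector(result.r, result.mask, min_size, seed)
    elif detector == "graph-community":
        memberships = _graph_community_detector(result.r, result.mask, min_size, seed)
    else:
        raise ValueError(f"unknown detector {detector!r}")
    return [Assembly(members=m, epoch=epoch) for m in memberships]


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def _hull_area(points: np.ndarray) -> float:
    try:
        return float(ConvexHull(points).volume)  # 2-D: volume is the area
    except (QhullError, ValueError):
        return np.nan


def assembly_statistics(
    assembly: Assembly,
    positions: np.ndarray,
    ap_axis: ApAxis,
    tuning_table: Optional[pd.DataFrame] = None,
) -> Assembly:
    """Fill an assembly's spatial and tuning summary fields (in place).

    com_ap is the centre of mass projected on the AP axis, clipped to [0, 1];
    coverage is the members' convex-hull area as a fraction of the hull area
    of all recorded cells; tuning statistics use the preferred stimuli of the
    assembly's selective members (defined only when there are >= 2).
    """
    positions = np.asarray(positions, dtype=float)
    pts = positions[assembly.members]
    assembly.com_xy = pts.mean(axis=0)
    assembly.com_ap = float(np.clip(ap_axis.project(assembly.com_xy), 0.0, 1.0))
    if len(pts) >= 3:
        member_area = _hull_area(pts)
        total_area = _hull_area(positions)
        if np.isfinite(member_area) and np.isfinite(total_area) and total_area > 0:
            assembly.coverage = member_area / total_area
    if tuning_table is not None:
        sel = tuning_table.loc[
            tuning_table.index.isin(assembly.members) & tuning_table["selective"]
        ]
        if len(sel) >= 2:
            pref = sel["preferred_deg"].to_numpy()
            assembly.mean_tuning_deg = float(pref.mean())
            assembly.tuning_variance_deg2 = float(pref.var(ddof=1))
    return assembly


def assembly_overlap(
    set_a: Sequence[Assembly],
    set_b: Sequence[Assembly],
    normalization: str = "min",
    matching: str = "best",
) -> float:
    """Mean membership overlap between two assembly sets.

    ``overlap(A, B) = |A & B| / min(|A|, |B|)`` (or Jaccard with
    ``normalization='jaccard'``); each assembly of ``set_a`` is credited with
    its best match in ``set_b`` (``matching='hungarian'`` enforces a
    one-to-one assignment) and the mean over ``set_a`` is returned.  Either
    set empty gives NaN.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        return np.nan
    mat = np.zeros((len(set_a), len(set_b)))
    for i, a in enumerate(set_a):
        sa = set(a.members.tolist())
        for j, b in enumerate(set_b):
            sb = set(b.members.tolist())
            inter = len(sa & sb)
            denom = min(len(sa), len(sb)) if normalization == "min" else len(sa | sb)
            mat[i, j] = inter / denom if denom else 0.0
    if matching == "best":
        return float(mat.max(axis=1).mean())
    if matching == "hungarian":
        ri, ci = linear_sum_assignment(-mat)
        scores = np.zeros(len(set_a))
        scores[ri] = mat[ri, ci]
        return float(scores.mean())
    raise ValueError(f"unknown matching {matching!r}")


def assembly_table(assemblies: Sequence[Assembly]) -> pd.DataFrame:
    """Tidy per-assembly table of all summary statistics."""
    rows = []
    for k, a in enumerate(assemblies):
        rows.append(
            {
                "assembly_id": k,
                "epoch": a.epoch,
                "size": a.size,
                "com_x_um": np.nan if a.com_xy is None else a.com_xy[0],
                "com_y_um": np.nan if a.com_xy is None else a.com_xy[1],
                "com_ap": a.com_ap,
                "coverage": a.coverage,
                "mean_tuning_deg": a.mean_tuning_deg,
                "tuning_variance_deg2": a.tuning_variance_deg2,
                "members": " ".join(map(str, a.members.tolist())),
            }
        )
    return pd.DataFrame(rows)
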