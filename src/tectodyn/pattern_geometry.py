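"""High-coactivity patterns, dimensionality, and pattern-subspace geometry.

A frame's coactivity level is the number of simultaneously active neurons in
the binary raster.  Significance is assessed against row-shuffle surrogates
(each neuron's active time bins are permuted independently, preserving its
activation count); the threshold is the smallest count whose pooled surrogate
tail falls below the significance level.  Frames at or above the threshold
that are strict local maxima of the coactivity series define the population
patterns of their epoch.

The patterns of an epoch span a linear subspace H with orthonormal basis
u_1..u_K (columns of U); P = U U^T projects onto H and the fraction of a
pattern p orthogonal to H is ||(1 - P) p|| / ||p|| — the part of p that the
epoch's activity cannot explain.  The balanced analysis resamples an equal
number of patterns per epoch (uniformly for the spontaneous pools,
consecutive runs for the evoked pool so all stimuli stay represented) and
averages the unexplained fractions over repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .preprocessing import (
    EPOCH_EA,
    EPOCH_NONE,
    EPOCH_SA,
    EPOCH_SE,
    BinaryRaster,
    EpochLabels,
)

__all__ = [
    "CoactivitySeries",
    "PatternSet",
    "PatternSubspace",
    "coactivity_threshold",
    "select_patterns",
    "mean_coactivity",
    "pca_dimensionality",
    "epoch_cosine_similarity",
    "build_subspace",
    "unexplained_fraction",
    "balanced_projection_analysis",
]

PATTERN_EPOCHS = (EPOCH_EA, EPOCH_SA, EPOCH_SE)


@dataclass
class CoactivitySeries:
    """Per-frame coactive-neuron counts and the shuffle-derived threshold."""

    counts: np.ndarray
    threshold: int
    alpha: float = 0.05
    null_tail_fraction: float = np.nan  # pooled surrogate mass at/above threshold

    def significant_frames(self) -> np.ndarray:
        return np.flatnonzero(self.counts >= self.threshold)


@dataclass
class PatternSet:
    """High-coactivity population vectors of one epoch."""

    epoch: str
    patterns: np.ndarray  # n_patterns x n_neurons
    frames: np.ndarray  # source frame indices

    def __post_init__(self) -> None:
        self.patterns = np.atleast_2d(np.asarray(self.patterns, dtype=float))
        self.frames = np.asarray(self.frames, dtype=int)

    def __len__(self) -> int:
        return self.patterns.shape[0]


@dataclass
class PatternSubspace:
    """Orthonormal basis U of the span of a pattern set; P = U U^T."""

    U: np.ndarray  # N x K, orthonormal columns

    @property
    def dim(self) -> int:
        return self.U.shape[1]

    @property
    def projector(self) -> np.ndarray:
        return self.U @ self.U.T

    def project(self, p: np.ndarray) -> np.ndarray:
        return self.U @ (self.U.T @ p)


# ---------------------------------------------------------------------------
# coactivity threshold and pattern selection
# ---------------------------------------------------------------------------


def coactivity_threshold(
    raster: BinaryRaster,
    n_shuffles: int = 500,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    method: str = "pooled",
) -> CoactivitySeries:
    """Shuffle-null significance threshold for per-frame coactivity counts.

    Each surrogate permutes every neuron's time bins independently (within
    rows), preserving per-neuron activation counts exactly.  With the default
    pooled null the threshold is the smallest count c such that the fraction
    of all surrogate frames with count >= c is below ``alpha``; with
    ``method='per_surrogate_max'`` the tail is the fraction of surrogates
    whose maximum count reaches c.  Frames with count >= threshold are
    significant.
    """
    B = np.asarray(raster.B)
    if B.size == 0:
        raise ValueError("raster is empty")
    n, t = B.shape
    counts = B.sum(axis=0).astype(int)
    if B.sum() == 0:
        return CoactivitySeries(counts=counts, threshold=1, alpha=alpha,
                                null_tail_fraction=0.0)
    rng = np.random.default_rng(seed)
    hist = np.zeros(n + 2, dtype=np.int64)
    max_counts = np.empty(n_shuffles, dtype=int)
    for s in range(n_shuffles):
        surr_counts = rng.permuted(B, axis=1).sum(axis=0)
        if method == "pooled":
            hist += np.bincount(surr_counts, minlength=n + 2)
        max_counts[s] = surr_counts.max()
    if method == "pooled":
        tail = hist[::-1].cumsum()[::-1] / (n_shuffles * t)
    elif method == "per_surrogate_max":
        tail = np.array(
            [(max_counts >= c).mean() for c in range(n + 2)]
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    above = np.flatnonzero(tail < alpha)
    thr = int(above[0]) if len(above) else n + 1
    thr = max(thr, 1)
    return CoactivitySeries(counts=counts, threshold=thr, alpha=alpha,
                            null_tail_fraction=float(tail[thr]))


def _peak_frames(counts: np.ndarray, threshold: int) -> np.ndarray:
    """Strict local maxima of the count series (plateaus -> first frame)."""
    peaks = []
    t = len(counts)
    i = 0
    while i < t:
        j = i
        while j + 1 < t and counts[j + 1] == counts[i]:
            j += 1
        left = counts[i - 1] if i > 0 else -np.inf
        right = counts[j + 1] if j + 1 < t else -np.inf
        if counts[i] > left and counts[i] > right and counts[i] >= threshold:
            peaks.append(i)
        i = j + 1
    return np.asarray(peaks, dtype=int)


def select_patterns(
    series: CoactivitySeries,
    raster: BinaryRaster,
    epoch_labels: EpochLabels,
    use_dff: Optional[np.ndarray] = None,
) -> Dict[str, PatternSet]:
    """High-coactivity patterns per epoch.

    Pattern frames are strict local maxima of the coactivity series (the
    first frame of a plateau) at or above the threshold; the pattern is the
    binary population vector at that frame (or the dF/F vector when
    ``use_dff`` is given).  Frames labelled none are discarded.
    """
    frames = _peak_frames(np.asarray(series.counts), series.threshold)
    source = np.asarray(use_dff if use_dff is not None else raster.B, dtype=float)
    out: Dict[str, PatternSet] = {}
    for epoch in PATTERN_EPOCHS:
        sel = frames[epoch_labels.labels[frames] == epoch]
        out[epoch] = PatternSet(
            epoch=epoch,
            patterns=source[:, sel].T if len(sel) else np.empty((0, source.shape[0])),
            frames=sel,
        )
    return out


def mean_coactivity(
    series: CoactivitySeries, pattern_sets: Dict[str, PatternSet]
) -> Dict[str, float]:
    """Mean coactivity count over each epoch's selected pattern frames."""
    out = {}
    for epoch, ps in pattern_sets.items():
        out[epoch] = (
            float(series.counts[ps.frames].mean()) if len(ps) else np.nan
        )
    return out


# ---------------------------------------------------------------------------
# dimensionality and similarity
# ---------------------------------------------------------------------------


def pca_dimensionality(
    dff: np.ndarray,
    epoch_frames: Sequence[int],
    variance_fraction: float = 0.8,
) -> int:
    """Number of principal components explaining ``variance_fraction``.

    Computed from the eigenspectrum of the epoch-restricted, mean-centred
    activity (frames as observations, neurons as variables).
    """
    X = np.asarray(dff, dtype=float)[:, np.asarray(epoch_frames)]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 frames")
    Xc = X - X.mean(axis=1, keepdims=True)
    s = np.linalg.svd(Xc, compute_uv=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        raise ValueError("epoch has zero total variance")
    cum = np.cumsum(var) / total
    return int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)


def epoch_cosine_similarity(
    set_a: PatternSet, set_b: PatternSet, best_match: bool = False
) -> float:
    """Cosine similarity between two epochs' pattern sets.

    Mean over all cross-set pattern pairs (``best_match`` instead averages
    each pattern's best counterpart).  Zero patterns are excluded with a
    warning.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("both pattern sets must be non-empty")

    def _unit(ps: PatternSet) -> np.ndarray:
        norms = np.linalg.norm(ps.patterns, axis=1)
        if (norms == 0).any():
            warnings.warn(
                f"{int((norms == 0).sum())} zero pattern(s) excluded from "
                f"{ps.epoch} cosine similarity",
                stacklevel=3,
            )
        keep = norms > 0
        return ps.patterns[keep] / norms[keep][:, None]

    ua, ub = _unit(set_a), _unit(set_b)
    if len(ua) == 0 or len(ub) == 0:
        raise ValueError("no non-zero patterns to compare")
    sims = ua @ ub.T
    return float(sims.max(axis=1).mean()) if best_match else float(sims.mean())


# ---------------------------------------------------------------------------
# subspace projection
# ---------------------------------------------------------------------------


def build_subspace(patterns: np.ndarray, rel_tol: float = 1e-10) -> PatternSubspace:
    """Orthonormal basis of the span of the given patterns (rows).

    K is the numerical rank: singular values above ``rel_tol`` times the
    largest are retained.
    """
    if isinstance(patterns, PatternSet):
        patterns = patterns.patterns
    M = np.atleast_2d(np.asarray(patterns, dtype=float)).T  # N x n_patterns
    if M.size == 0 or not np.linalg.norm(M) > 0:
        raise ValueError("cannot build a subspace from all-zero patterns")
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    k = int((s > rel_tol * s[0]).sum())
    return PatternSubspace(U=U[:, :k])


def unexplained_fraction(p: np.ndarray, subspace: PatternSubspace) -> float:
    """||(1 - P) p|| / ||p||: the fraction of p orthogonal to the subspace."""
    p = np.asarray(p, dtype=float).ravel()
    norm = np.linalg.norm(p)
    if norm == 0:
        raise ValueError("cannot project a zero pattern")
    resid = p - subspace.project(p)
    return float(np.clip(np.linalg.norm(resid) / norm, 0.0, 1.0))


def balanced_projection_analysis(
    pattern_sets: Dict[str, PatternSet],
    n_select: Optional[int] = None,
    n_repeats: int = 200,
    seed: Optional[int] = None,
):
    """Cross-epoch unexplained fractions with balanced pattern selection.

    Per repeat, ``n_select`` patterns are drawn from each epoch's pool — SA
    and SE uniformly without replacement, EA as a consecutive run starting at
    a uniform index (no wrap) so the run covers all stimuli roughly equally.
    Each epoch's subspace is built from its selected patterns and every
    pattern of each *other* epoch's full pool is projected onto it; fractions
    are averaged over patterns, then over repeats.

    Returns ``(pairs, summary)``: a tidy DataFrame of ordered
    (target_epoch, subspace_epoch) means, and the aggregate
    ``{'1 - P_EA', '1 - P_SA', '1 - P_SE'}`` (pooled over the two target
    epochs of each subspace).
    """
    for epoch in PATTERN_EPOCHS:
        if epoch not in pattern_sets or len(pattern_sets[epoch]) == 0:
            raise ValueError(f"missing patterns for epoch {epoch}")
    pools = {e: pattern_sets[e].patterns for e in PATTERN_EPOCHS}
    sizes = {e: len(v) for e, v in pools.items()}
    if n_select is None:
        n_select = min(sizes.values())
    if any(n_select > s for s in sizes.values()):
        raise ValueError(
            f"n_select={n_select} exceeds a pattern pool "
            f"(sizes {sizes}); lower n_select"
        )
    rng = np.random.default_rng(seed)
    acc = {(tgt, sub): 0.0 for sub in PATTERN_EPOCHS for tgt in PATTERN_EPOCHS
           if tgt != sub}
    for _ in range(n_repeats):
        selected = {}
        for e in (EPOCH_SA, EPOCH_SE):
            idx = rng.choice(sizes[e], size=n_select, replace=False)
            selected[e] = pools[e][idx]
        start = rng.integers(0, sizes[EPOCH_EA] - n_select + 1)
        selected[EPOCH_EA] = pools[EPOCH_EA][start: start + n_select]
        for sub_epoch in PATTERN_EPOCHS:
            sub = build_subspace(selected[sub_epoch])
            for tgt_epoch in PATTERN_EPOCHS:
                if tgt_epoch == sub_epoch:
                    continue
                P = pools[tgt_epoch]
                resid = P - (P @ sub.U) @ sub.U.T
                fr = np.linalg.norm(resid, axis=1) / np.linalg.norm(P, axis=1)
                acc[(tgt_epoch, sub_epoch)] += float(np.clip(fr, 0, 1).mean())
    rows = [
        {
            "target_epoch": tgt,
            "subspace_epoch": sub,
            "mean_unexplained": v / n_repeats,
            "n_select": int(n_select),
            "n_repeats": int(n_repeats),
        }
        for (tgt, sub), v in acc.items()
    ]
    pairs = pd.DataFrame(rows)
    summary = {}
    for sub_epoch in PATTERN_EPOCHS:
        others = [e for e in PATTERN_EPOCHS if e != sub_epoch]
        weights = np.array([sizes[e] for e in others], dtype=float)
        vals = np.array(
            [
                pairs.loc[
                    (pairs["target_epoch"] == e)
                    & (pairs["subspace_epoch"] == sub_epoch),
                    "mean_unexplained",
                ].iloc[0]
                for e in others
            ]
        )
        summary[f"1 - P_{sub_epoch}"] = float((vals * weights).sum() / weights.sum())
    return pairs, summary
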