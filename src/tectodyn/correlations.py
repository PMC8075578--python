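"""Pairwise correlation structure with SHIFT-surrogate significance.

Significance of pairwise Pearson correlations is assessed against a null in
which every neuron's trace is independently circularly time-shifted: the
within-neuron temporal structure is preserved exactly while between-neuron
alignment is destroyed.  Observed coefficients above the 95th percentile of
the pooled null distribution are deemed significant (one-sided, positive
correlations only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

__all__ = [
    "CorrelationResult",
    "pairwise_correlations",
    "shift_null_mask",
    "distance_binned_profile",
    "matrix_similarity",
]


@dataclass
class CorrelationResult:
    """Correlation matrix, optional significance mask and its null cutoff."""

    r: np.ndarray
    mask: Optional[np.ndarray] = None
    null_percentile_value: Optional[float] = None
    epoch: Optional[str] = None

    @property
    def n_neurons(self) -> int:
        return self.r.shape[0]

    def significant_fraction(self) -> float:
        """Fraction of valid (finite) pairs flagged significant."""
        if self.mask is None:
            raise ValueError("mask not set; run shift_null_mask")
        iu = np.triu_indices(self.n_neurons, k=1)
        valid = np.isfinite(self.r[iu])
        return float(self.mask[iu][valid].mean())


def _corr_matrix(X: np.ndarray) -> np.ndarray:
    """Pearson correlation across rows; zero-variance rows give NaN."""
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    ok = sd > 0
    Z = np.zeros_like(Xc)
    Z[ok] = Xc[ok] / sd[ok][:, None]
    r = (Z @ Z.T) / X.shape[1]
    r[~ok, :] = np.nan
    r[:, ~ok] = np.nan
    np.fill_diagonal(r, np.where(ok, 1.0, np.nan))
    return np.clip(r, -1.0, 1.0, out=r)


def pairwise_correlations(
    dff: np.ndarray, epoch_frames: Sequence[int], epoch: Optional[str] = None
) -> CorrelationResult:
    """Pearson correlations between all neuron pairs on the given frames.

    Zero-variance neurons get NaN rows/columns and are excluded downstream.
    """
    dff = np.asarray(dff, dtype=float)
    frames = np.asarray(epoch_frames)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to correlate")
    return CorrelationResult(r=_corr_matrix(dff[:, frames]), epoch=epoch)


def shift_null_mask(
    dff: np.ndarray,
    epoch_frames: Sequence[int],
    n_shuffles: int = 1000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    epoch: Optional[str] = None,
) -> CorrelationResult:
    """Significance mask from circular-shift surrogates, pooled null.

    Each surrogate shifts every neuron's epoch trace circularly by an
    independent uniform offset (at least one frame).  All pairwise
    coefficients across all surrogates form one pooled null distribution and
    the observed matrix is thresholded at its ``1 - alpha`` percentile.
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be >= 20 for a stable percentile")
    dff = np.asarray(dff, dtype=float)
    frames = np.asarray(epoch_frames)
    if len(frames) < 10:
        raise ValueError("epoch must contain at least 10 frames")
    X = dff[:, frames]
    n, t = X.shape
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    base = np.arange(t)
    null = np.empty((n_shuffles, len(iu[0])))
    rows = np.arange(n)[:, None]
    for s in range(n_shuffles):
        offsets = rng.integers(1, t, size=n)
        shifted = X[rows, (base[None, :] + offsets[:, None]) % t]
        null[s] = _corr_matrix(shifted)[iu]
    pool = null[np.isfinite(null)]
    # no valid pairs at all (e.g. every neuron silent): nothing can be significant
    cutoff = float(np.percentile(pool, 100 * (1 - alpha))) if pool.size else np.inf
    r = _corr_matrix(X)
    mask = np.zeros_like(r, dtype=bool)
    with np.errstate(invalid="ignore"):
        mask[iu] = r[iu] > cutoff
    mask |= mask.T
    np.fill_diagonal(mask, False)
    mask &= np.isfinite(r)
    return CorrelationResult(r=r, mask=mask, null_percentile_value=cutoff, epoch=epoch)


def distance_binned_profile(
    result: CorrelationResult,
    positions: np.ndarray,
    bin_edges_um: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Mean significant correlation per pairwise-distance bin.

    Bins are half-open ``[lo, hi)``; by default 50-um bins up to the maximum
    pairwise distance.  Only pairs flagged significant contribute; empty bins
    give NaN.
    """
    if result.mask is None:
        raise ValueError("result has no significance mask")
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] != result.n_neurons:
        raise ValueError("positions must cover every neuron")
    d = squareform(pdist(positions))
    iu = np.triu_indices(result.n_neurons, k=1)
    dist, rvals, sig = d[iu], result.r[iu], result.mask[iu]
    if bin_edges_um is None:
        top = max(float(dist.max()), 50.0)
        bin_edges_um = np.arange(0.0, top + 50.0, 50.0)
    edges = np.asarray(bin_edges_um, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (dist >= lo) & (dist < hi) & sig & np.isfinite(rvals)
        rows.append(
            {
                "bin_lo_um": lo,
                "bin_hi_um": hi,
                "mean_r": float(rvals[in_bin].mean()) if in_bin.any() else np.nan,
                "n_pairs": int(in_bin.sum()),
            }
        )
    return pd.DataFrame(rows)


def matrix_similarity(
    result_a: CorrelationResult,
    result_b: CorrelationResult,
    significant_only: bool = False,
) -> float:
    """Pearson correlation between two correlation matrices.

    The upper triangles (diagonal excluded) are vectorised and correlated;
    with ``significant_only`` the comparison is restricted to pairs
    significant in either matrix.
    """
    if result_a.r.shape != result_b.r.shape:
        raise ValueError("correlation matrices cover different neuron sets")
    iu = np.triu_indices(result_a.n_neurons, k=1)
    a, b = result_a.r[iu], result_b.r[iu]
    keep = np.isfinite(a) & np.isfinite(b)
    if significant_only:
        if result_a.mask is None or result_b.mask is None:
            raise ValueError("significant_only requires masks on both results")
        keep &= result_a.mask[iu] | result_b.mask[iu]
    if keep.sum() < 2:
        raise ValueError("not enough valid pairs to compare")
    return float(pearsonr(a[keep], b[keep])[0])
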