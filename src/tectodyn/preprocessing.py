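"""Core data model: dF/F, binarization and epoch segmentation.

The recording timeline is a dark spontaneous epoch (SA) followed by the
visual stimulation period.  Within the stimulation period each spot onset
defines an evoked window (EA, first 5 s post-onset) and a
spontaneous-within-evoked window (SE, 6-20 s post-onset); remaining frames
are unlabelled.  The whole stimulation period is referred to as TEA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .synthetic import StimulusLog, round_half_up

__all__ = [
    "Recording",
    "DffTraces",
    "BinaryRaster",
    "EpochLabels",
    "compute_dff",
    "binarize",
    "segment_epochs",
]

logger = logging.getLogger(__name__)

EPOCH_SA = "SA"
EPOCH_EA = "EA"
EPOCH_SE = "SE"
EPOCH_NONE = "none"


@dataclass
class Recording:
    """A population recording plus its spatial and stimulus metadata.

    Either raw fluorescence ``F`` or ``dff`` may be supplied; when ``dff`` is
    given directly the baseline step is skipped.
    """

    frame_rate_hz: float
    F: Optional[np.ndarray] = None
    dff: Optional[np.ndarray] = None
    positions: Optional[np.ndarray] = None
    neuropil_contour: Optional[np.ndarray] = None
    stimulus_log: Optional[StimulusLog] = None

    def __post_init__(self) -> None:
        data = self.dff if self.dff is not None else self.F
        if data is None:
            raise ValueError("Recording needs F or dff")
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError("trace matrix must be (N >= 2) x (T >= 2)")
        if self.dff is not None:
            self.dff = data
        else:
            self.F = data
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (data.shape[0], 2):
                raise ValueError("positions must have exactly one (x, y) row per neuron")

    @property
    def n_neurons(self) -> int:
        data = self.dff if self.dff is not None else self.F
        return data.shape[0]

    @property
    def n_frames(self) -> int:
        data = self.dff if self.dff is not None else self.F
        return data.shape[1]


@dataclass
class DffTraces:
    """dF/F traces with the baseline they were computed against."""

    dff: np.ndarray
    F0: np.ndarray

    def reconstruct_F(self) -> np.ndarray:
        return self.F0 * (1.0 + self.dff)


@dataclass
class BinaryRaster:
    """Binarized activity: B[i, t] = 1 iff dff[i, t] > mean_i + 2 sd_i."""

    B: np.ndarray
    thresholds: np.ndarray
    zero_variance: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_neurons(self) -> int:
        return self.B.shape[0]

    @property
    def n_frames(self) -> int:
        return self.B.shape[1]


@dataclass
class EpochLabels:
    """Per-frame epoch assignment and, for EA frames, the driving stimulus."""

    labels: np.ndarray  # '<U4' array of {SA, EA, SE, none}
    stimulus_position: np.ndarray  # degrees, NaN outside EA
    sa_end_frame: int

    def frames(self, epoch: str) -> np.ndarray:
        return np.flatnonzero(self.labels == epoch)

    def tea_frames(self) -> np.ndarray:
        """All frames of the stimulation (total evoked activity) period."""
        return np.arange(self.sa_end_frame, len(self.labels))

    def counts(self) -> dict:
        return {e: int((self.labels == e).sum())
                for e in (EPOCH_SA, EPOCH_EA, EPOCH_SE, EPOCH_NONE)}

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# dF/F
# ---------------------------------------------------------------------------


def compute_dff(
    F: np.ndarray,
    frame_rate_hz: float,
    window_s: float = 3.0,
    lower_fraction: float = 0.2,
    baseline_window_s: float = 30.0,
) -> DffTraces:
    """Time-varying-baseline dF/F.

    Per neuron, a smoothed baseline curve follows the lower ``lower_fraction``
    of samples (running 20th percentile over ``baseline_window_s``); F0(t) is
    the minimum of that curve in a ``window_s`` window centred on t (windows
    truncate at the edges).  dff = (F - F0) / F0.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim == 1:
        F = F[None, :]
    if (F < 0).any():
        raise ValueError("raw fluorescence must be non-negative")
    if window_s * frame_rate_hz < 1:
        raise ValueError("window_s x frame_rate_hz must be >= 1 frame")
    w_long = max(int(round_half_up(baseline_window_s * frame_rate_hz)), 1)
    w_min = max(int(round_half_up(window_s * frame_rate_hz)), 1)
    lower = ndimage.percentile_filter(F, percentile=lower_fraction * 100,
                                      size=(1, w_long), mode="nearest")
    F0 = ndimage.minimum_filter1d(lower, size=w_min, axis=1, mode="nearest")
    bad = np.nonzero((F0 <= 0).any(axis=1))[0]
    if len(bad):
        raise ValueError(
            f"baseline F0 is non-positive for neuron(s) {bad.tolist()}; "
            "dF/F is undefined"
        )
    return DffTraces(dff=(F - F0) / F0, F0=F0)


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------


def binarize(dff: np.ndarray) -> BinaryRaster:
    """Threshold each neuron at two standard deviations above its mean.

    Statistics are taken over the full recording so a single threshold serves
    all epochs; the inequality is strict, hence zero-variance neurons yield
    all-zero rows (flagged, not an error).
    """
    dff = np.asarray(dff, dtype=float)
    if not np.isfinite(dff).all():
        raise ValueError("dff must be finite")
    mean = dff.mean(axis=1)
    sd = dff.std(axis=1)
    thr = mean + 2.0 * sd
    zero_var = np.flatnonzero(sd == 0)
    if len(zero_var):
        logger.warning("neurons %s have zero variance; their rows are all-zero",
                       zero_var.tolist())
    B = (dff > thr[:, None]).astype(np.uint8)
    return BinaryRaster(B=B, thresholds=thr, zero_variance=zero_var)


# ---------------------------------------------------------------------------
# epoch segmentation
# ---------------------------------------------------------------------------


def segment_epochs(
    stimulus_log: Optional[StimulusLog],
    frame_rate_hz: float,
    n_frames: int,
    sa_end_frame: int,
    ea_window_s: tuple = (0.0, 5.0),
    se_window_s: tuple = (6.0, 20.0),
) -> EpochLabels:
    """Assign every frame to SA, EA, SE or none.

    SA is everything before ``sa_end_frame``.  For each onset frame f the EA
    window is ``[f + round(ea_lo*fps), f + round(ea_hi*fps)]`` (inclusive) and
    the SE window ``[f + round(se_lo*fps), f + round(se_hi*fps)]``; EA labels
    take precedence over SE, and where EA windows of distinct onsets overlap
    the later onset wins (with a warning).  With no stimuli all frames are SA.
    """
    labels = np.full(n_frames, EPOCH_NONE, dtype="<U4")
    labels[: min(sa_end_frame, n_frames)] = EPOCH_SA
    stim_pos = np.full(n_frames, np.nan)
    if stimulus_log is None or len(stimulus_log) == 0:
        labels[:] = EPOCH_SA
        return EpochLabels(labels=labels, stimulus_position=stim_pos,
                           sa_end_frame=n_frames)

    onsets = stimulus_log.onset_frame
    if (onsets < sa_end_frame).any():
        raise ValueError("stimulus onsets must lie after the SA epoch")

    r = round_half_up
    ea_lo, ea_hi = (r(x * frame_rate_hz) for x in ea_window_s)
    se_lo, se_hi = (r(x * frame_rate_hz) for x in se_window_s)

    for f in onsets:  # SE first so any EA pass wins
        a, b = f + se_lo, min(f + se_hi, n_frames - 1)
        if a < n_frames:
            labels[a: b + 1] = EPOCH_SE
    prev_end = -1
    for f, pos in zip(onsets, stimulus_log.position_deg):
        a, b = f + ea_lo, min(f + ea_hi, n_frames - 1)
        if a <= prev_end:
            warnings.warn(
                f"EA windows overlap at frame {a}; later onset takes precedence",
                stacklevel=2,
            )
        if a < n_frames:
            labels[a: b + 1] = EPOCH_EA
            stim_pos[a: b + 1] = pos
        prev_end = b
    return EpochLabels(labels=labels, stimulus_position=stim_pos,
                       sa_end_frame=sa_end_frame)
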