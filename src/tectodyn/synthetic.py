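"""Seeded synthetic tectal recordings with known ground truth.

The generator emulates the structure of a two-photon recording of the larval
zebrafish optic tectum: a dark (spontaneous) epoch followed by a visual
stimulation epoch of repeated trials of small spots at nine azimuthal
positions.  Spontaneous activity is organised into recurring assemblies
(groups of neurons that activate jointly); evoked activity is carried by
retinotopically tuned ensembles whose overlap with the spontaneous assemblies
is a single configuration knob.  Events are convolved with a single-
exponential calcium kernel and corrupted with additive Gaussian noise.

Every random draw descends from one seed, so identical configurations yield
bit-identical datasets.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "StimulusLog",
    "GroundTruth",
    "SyntheticDataset",
    "build_stimulus_schedule",
    "generate_dataset",
    "generate_movie",
    "round_half_up",
]

#: spot order used in the experiment: maximises angular separation of
#: consecutive spots within a trial.
DEFAULT_POSITIONS_DEG = (45.0, 120.0, 60.0, 135.0, 75.0, 150.0, 90.0, 165.0, 105.0)


class ConfigurationError(ValueError):
    """Raised for invalid simulation or pipeline configurations."""


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties away from zero (half-up for x >= 0).

    Used for all seconds -> frames conversions so that frame windows are
    reproducible and do not depend on banker's rounding.
    """
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of a synthetic recording.

    Defaults follow the experimental protocol: 2.2 Hz acquisition, 30 min of
    spontaneous activity in the dark, then 20 trials of nine 1-s spots
    (45°-165° in 15° steps, presented in an order maximising within-trial
    separation) with 20 s between spots and 25 s between trials.
    """

    n_neurons: int = 100
    frame_rate_hz: float = 2.2
    sa_duration_s: float = 1800.0
    n_trials: int = 20
    stimulus_positions_deg: Sequence[float] = DEFAULT_POSITIONS_DEG
    spot_on_s: float = 1.0
    gap_s: float = 20.0
    iti_s: float = 25.0
    n_sa_assemblies: int = 5
    n_ea_ensembles: int = 9
    sa_assembly_size: Optional[int] = None
    ea_ensemble_size: Optional[int] = None
    assembly_event_rate_hz: float = 0.02
    tuning_sd_deg: float = 15.0
    retinotopy_noise_deg: float = 5.0
    ea_sa_overlap: float = 0.5
    calcium_tau_s: float = 1.8
    noise_sd: float = 0.05
    sa_event_amplitude: float = 1.0
    evoked_amplitude: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ConfigurationError("n_neurons must be >= 2")
        for name in ("frame_rate_hz", "sa_duration_s", "spot_on_s", "gap_s",
                     "iti_s", "calcium_tau_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in ("assembly_event_rate_hz", "noise_sd", "retinotopy_noise_deg",
                     "sa_event_amplitude", "evoked_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.tuning_sd_deg <= 0:
            raise ConfigurationError("tuning_sd_deg must be strictly positive")
        if not 0.0 <= self.ea_sa_overlap <= 1.0:
            raise ConfigurationError("ea_sa_overlap must lie in [0, 1]")
        if self.n_trials < 0:
            raise ConfigurationError("n_trials must be >= 0")
        if self.n_sa_assemblies < 1 or self.n_ea_ensembles < 1:
            raise ConfigurationError("assembly/ensemble counts must be >= 1")
        self.stimulus_positions_deg = tuple(float(p) for p in self.stimulus_positions_deg)

    # resolved membership sizes -------------------------------------------
    @property
    def resolved_sa_assembly_size(self) -> int:
        if self.sa_assembly_size is not None:
            return int(self.sa_assembly_size)
        return max(2, round(0.45 * self.n_neurons / self.n_sa_assemblies))

    @property
    def resolved_ea_ensemble_size(self) -> int:
        if self.ea_ensemble_size is not None:
            return int(self.ea_ensemble_size)
        return max(2, round(0.55 * self.n_neurons / self.n_ea_ensembles))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stimulus_positions_deg"] = list(self.stimulus_positions_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# stimulus schedule
# ---------------------------------------------------------------------------


@dataclass
class StimulusLog:
    """One record per spot presentation.

    ``onset_time_s`` is measured from the start of whatever epoch the log was
    built for (the evoked epoch for :func:`build_stimulus_schedule`, the whole
    recording inside a :class:`SyntheticDataset`);
    ``onset_frame = round_half_up(onset_time_s * frame_rate_hz)``.
    """

    trial: np.ndarray
    position_deg: np.ndarray
    onset_time_s: np.ndarray
    onset_frame: np.ndarray

    def __post_init__(self) -> None:
        self.trial = np.asarray(self.trial, dtype=int)
        self.position_deg = np.asarray(self.position_deg, dtype=float)
        self.onset_time_s = np.asarray(self.onset_time_s, dtype=float)
        self.onset_frame = np.asarray(self.onset_frame, dtype=int)
        if len(self.onset_time_s) > 1 and not np.all(np.diff(self.onset_time_s) > 0):
            raise ValueError("stimulus onset times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onset_time_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial,
                "position_deg": self.position_deg,
                "onset_time_s": self.onset_time_s,
                "onset_frame": self.onset_frame,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StimulusLog":
        return cls(
            trial=df["trial"].to_numpy(),
            position_deg=df["position_deg"].to_numpy(),
            onset_time_s=df["onset_time_s"].to_numpy(),
            onset_frame=df["onset_frame"].to_numpy(),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StimulusLog":
        return cls.from_frame(pd.read_csv(path))

    def shifted(self, offset_s: float, frame_rate_hz: float) -> "StimulusLog":
        """Return a copy with onsets offset by ``offset_s`` (absolute times)."""
        t = self.onset_time_s + offset_s
        return StimulusLog(
            trial=self.trial,
            position_deg=self.position_deg,
            onset_time_s=t,
            onset_frame=np.array([round_half_up(x * frame_rate_hz) for x in t]),
        )


def build_stimulus_schedule(config: SimulationConfig) -> StimulusLog:
    """Spot presentation schedule, times relative to the evoked-epoch start.

    Within a trial consecutive onsets are separated by ``spot_on_s + gap_s``;
    consecutive trials are additionally separated by ``iti_s``.  The default
    protocol yields 20 x 9 = 180 presentations.
    """
    positions = config.stimulus_positions_deg
    step = config.spot_on_s + config.gap_s
    trial_span = len(positions) * step
    trials, pos, times = [], [], []
    for tr in range(config.n_trials):
        t0 = tr * (trial_span + config.iti_s)
        for j, p in enumerate(positions):
            trials.append(tr)
            pos.append(p)
            times.append(t0 + j * step)
    times = np.asarray(times, dtype=float)
    frames = np.array([round_half_up(t * config.frame_rate_hz) for t in times], dtype=int)
    return StimulusLog(np.asarray(trials), np.asarray(pos), times, frames)


# ---------------------------------------------------------------------------
# ground truth and dataset containers
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    sa_assembly_membership: list  # list of int arrays
    ea_ensemble_membership: list  # list of int arrays
    ensemble_position_deg: np.ndarray  # stimulus position driving each ensemble
    true_preferred_deg: np.ndarray  # per neuron
    responsive_neurons: np.ndarray  # union of ensemble members
    true_event_times: list  # per SA assembly, seconds from recording start
    roi_masks: Optional[list] = None  # per neuron boolean (H, W), movie mode

    def to_json(self, path) -> None:
        obj = {
            "sa_assembly_membership": [np.asarray(m).tolist() for m in self.sa_assembly_membership],
            "ea_ensemble_membership": [np.asarray(m).tolist() for m in self.ea_ensemble_membership],
            "ensemble_position_deg": np.asarray(self.ensemble_position_deg).tolist(),
            "true_preferred_deg": np.asarray(self.true_preferred_deg).tolist(),
            "responsive_neurons": np.asarray(self.responsive_neurons).tolist(),
            "true_event_times": [np.asarray(t).tolist() for t in self.true_event_times],
            "roi_masks": None
            if self.roi_masks is None
            else [np.argwhere(m).tolist() for m in self.roi_masks],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path, movie_shape=None) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        masks = None
        if obj.get("roi_masks") is not None and movie_shape is not None:
            masks = []
            for px in obj["roi_masks"]:
                m = np.zeros(movie_shape, dtype=bool)
                if px:
                    idx = np.asarray(px, dtype=int)
                    m[idx[:, 0], idx[:, 1]] = True
                masks.append(m)
        return cls(
            sa_assembly_membership=[np.asarray(m, dtype=int) for m in obj["sa_assembly_membership"]],
            ea_ensemble_membership=[np.asarray(m, dtype=int) for m in obj["ea_ensemble_membership"]],
            ensemble_position_deg=np.asarray(obj["ensemble_position_deg"], dtype=float),
            true_preferred_deg=np.asarray(obj["true_preferred_deg"], dtype=float),
            responsive_neurons=np.asarray(obj["responsive_neurons"], dtype=int),
            true_event_times=[np.asarray(t, dtype=float) for t in obj["true_event_times"]],
            roi_masks=masks,
        )


@dataclass
class SyntheticDataset:
    """A complete synthetic recording: the universal pipeline input."""

    traces: np.ndarray  # dF/F, neurons x frames
    positions: np.ndarray  # neurons x 2, micrometres
    neuropil_contour: np.ndarray  # polygon vertices x 2, micrometres
    stimulus_log: StimulusLog  # absolute recording time
    frame_rate_hz: float
    sa_end_frame: int
    ground_truth: GroundTruth
    config: SimulationConfig

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def save(self, out_dir) -> None:  # thin forwarding; io owns formats
        from . import io as _io

        _io.save_dataset(self, out_dir)


# ---------------------------------------------------------------------------
# membership and geometry construction
# ---------------------------------------------------------------------------

# Neuropil ellipse used for all synthetic fish.  Deliberately rotated so the
# anterior-posterior axis fit downstream is exercised non-trivially.
_NP_CENTER = np.array([150.0, 100.0])
_NP_SEMI_MAJOR = 120.0
_NP_SEMI_MINOR = 60.0
_NP_ANGLE_RAD = math.radians(20.0)


def _neuropil_contour(n_vertices: int = 72) -> np.ndarray:
    phi = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    u = np.array([math.cos(_NP_ANGLE_RAD), math.sin(_NP_ANGLE_RAD)])
    w = np.array([-math.sin(_NP_ANGLE_RAD), math.cos(_NP_ANGLE_RAD)])
    return (
        _NP_CENTER
        + _NP_SEMI_MAJOR * np.cos(phi)[:, None] * u
        + _NP_SEMI_MINOR * np.sin(phi)[:, None] * w
    )


def _build_memberships(config: SimulationConfig, rng: np.random.Generator):
    """SA assemblies (disjoint), EA ensembles and their paired assemblies.

    An EA ensemble k is driven by stimulus position theta_k; a fraction
    ``ea_sa_overlap`` of its members is drawn from the spontaneous assembly
    whose home angle is nearest theta_k, the rest from neurons belonging to no
    assembly.  Pool draws are global without replacement so that at
    ``ea_sa_overlap = 0`` ensembles and assemblies are fully disjoint.
    """
    n = config.n_neurons
    n_sa = config.n_sa_assemblies
    n_ea = config.n_ea_ensembles
    sa_size = config.resolved_sa_assembly_size
    ea_size = config.resolved_ea_ensemble_size
    if n_sa * sa_size > n:
        raise ConfigurationError("SA assemblies do not fit into n_neurons")

    perm = rng.permutation(n)
    assemblies = [np.sort(perm[j * sa_size:(j + 1) * sa_size]) for j in range(n_sa)]
    pool = list(perm[n_sa * sa_size:])

    pos_sorted = np.sort(np.unique(config.stimulus_positions_deg))
    if n_ea == 1:
        thetas = np.array([pos_sorted[len(pos_sorted) // 2]])
    else:
        idx = np.round(np.linspace(0, len(pos_sorted) - 1, n_ea)).astype(int)
        thetas = pos_sorted[idx]
    home = np.linspace(pos_sorted[0], pos_sorted[-1], n_sa)

    n_keep = round(config.ea_sa_overlap * ea_size)
    n_new = ea_size - n_keep
    if n_keep > sa_size:
        raise ConfigurationError(
            "ea_ensemble_size * ea_sa_overlap exceeds sa_assembly_size"
        )
    if n_ea * n_new > len(pool):
        raise ConfigurationError(
            "not enough unassigned neurons to build disjoint ensemble parts; "
            "reduce ea_ensemble_size or raise ea_sa_overlap"
        )

    ensembles = []
    paired = []
    for k in range(n_ea):
        j = int(np.argmin(np.abs(home - thetas[k])))
        paired.append(j)
        members = []
        if n_keep > 0:
            members.extend(rng.choice(assemblies[j], size=n_keep, replace=False))
        for _ in range(n_new):
            members.append(pool.pop(0))
        ensembles.append(np.sort(np.asarray(members, dtype=int)))
    return assemblies, ensembles, thetas, home, paired


def _assign_preferred(config, rng, assemblies, ensembles, thetas, home):
    """True preferred angle per neuron (retinotopy with Gaussian jitter)."""
    pos_sorted = np.sort(np.unique(config.stimulus_positions_deg))
    lo, hi = pos_sorted[0], pos_sorted[-1]
    n = config.n_neurons
    pref = rng.uniform(lo, hi, size=n)
    in_ensemble = np.zeros(n, dtype=bool)
    for j, asm in enumerate(assemblies):
        pref[asm] = home[j] + rng.normal(0.0, config.retinotopy_noise_deg, size=len(asm))
    for k, ens in enumerate(ensembles):
        pref[ens] = thetas[k] + rng.normal(0.0, config.retinotopy_noise_deg, size=len(ens))
        in_ensemble[ens] = True
    return pref, in_ensemble


def _place_neurons(config, rng, pref) -> np.ndarray:
    """Neuron positions: AP coordinate is a linear map of preferred angle.

    Cell bodies sit in a band inside the neuropil ellipse; position along the
    major (anterior-posterior) axis follows the retinotopic map, the minor-
    axis coordinate is uniform scatter.
    """
    pos_sorted = np.sort(np.unique(config.stimulus_positions_deg))
    lo, hi = pos_sorted[0], pos_sorted[-1]
    span = max(hi - lo, 1e-9)
    t = np.clip((pref - lo) / span, 0.0, 1.0)
    t = np.clip(t + rng.normal(0.0, 0.03, size=len(pref)), 0.0, 1.0)
    v = rng.uniform(-1.0, 1.0, size=len(pref))
    u = np.array([math.cos(_NP_ANGLE_RAD), math.sin(_NP_ANGLE_RAD)])
    w = np.array([-math.sin(_NP_ANGLE_RAD), math.cos(_NP_ANGLE_RAD)])
    return (
        _NP_CENTER
        + (2 * t - 1)[:, None] * (0.9 * _NP_SEMI_MAJOR) * u
        + v[:, None] * (0.7 * _NP_SEMI_MINOR) * w
    )


# ---------------------------------------------------------------------------
# trace synthesis
# ---------------------------------------------------------------------------


def _calcium_kernel(config: SimulationConfig) -> np.ndarray:
    dt = 1.0 / config.frame_rate_hz
    n = int(math.ceil(5.0 * config.calcium_tau_s / dt)) + 1
    return np.exp(-np.arange(n) * dt / config.calcium_tau_s)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic recording (dF/F traces + ground truth).

    The trace matrix covers the spontaneous epoch followed by the evoked
    epoch.  Spontaneous assembly events activate all member neurons jointly
    (with per-neuron amplitude jitter) and continue throughout the evoked
    epoch, providing the spontaneous-within-evoked component.  Evoked
    responses are restricted to ensemble members and scale with a Gaussian of
    the angular distance between the neuron's true preferred position and the
    presented spot.  All events are convolved with an exponential calcium
    kernel and white noise is added.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_mem, rng_ret, rng_pos, rng_ev, rng_stim, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    assemblies, ensembles, thetas, home, _ = _build_memberships(config, rng_mem)
    pref, _ = _assign_preferred(config, rng_ret, assemblies, ensembles, thetas, home)
    positions = _place_neurons(config, rng_pos, pref)
    contour = _neuropil_contour()

    fps = config.frame_rate_hz
    sa_end = round_half_up(config.sa_duration_s * fps)
    rel_log = build_stimulus_schedule(config)
    if len(rel_log) > 0:
        evoked_span_s = rel_log.onset_time_s[-1] + config.spot_on_s + config.gap_s
        log = rel_log.shifted(config.sa_duration_s, fps)
    else:
        evoked_span_s = 0.0
        log = rel_log
    n_frames = sa_end + round_half_up(evoked_span_s * fps)
    total_s = n_frames / fps

    impulses = np.zeros((config.n_neurons, n_frames), dtype=float)

    # evoked windows are stimulus-dominated: the ongoing spontaneous assembly
    # process runs over the whole recording except around each onset (from
    # three decay constants before, so calcium tails do not leak into the
    # evoked window, until 5 s after); it continues between stimuli,
    # yielding SE activity
    ea_mask = np.zeros(n_frames, dtype=bool)
    ea_len = round_half_up(5.0 * fps)
    guard = round_half_up(3.0 * config.calcium_tau_s * fps)
    for f in log.onset_frame:
        ea_mask[max(f - guard, 0): min(f + ea_len + 1, n_frames)] = True

    event_times = []
    for asm in assemblies:
        n_ev = rng_ev.poisson(config.assembly_event_rate_hz * total_s)
        times = np.sort(rng_ev.uniform(0.0, total_s, size=n_ev))
        frames = np.minimum((times * fps).astype(int), n_frames - 1)
        keep = ~ea_mask[frames]
        times, frames = times[keep], frames[keep]
        for f in frames:
            impulses[asm, f] += config.sa_event_amplitude * rng_ev.uniform(
                0.8, 1.2, size=len(asm)
            )
        event_times.append(times)

    # evoked responses: retinotopically tuned ensemble members
    responsive = np.unique(np.concatenate(ensembles)) if ensembles else np.array([], int)
    two_sq = 2.0 * config.tuning_sd_deg ** 2
    for theta, f in zip(log.position_deg, log.onset_frame):
        if f >= n_frames:
            continue
        gains = np.exp(-((pref[responsive] - theta) ** 2) / two_sq)
        jitter = rng_stim.uniform(0.8, 1.2, size=len(responsive))
        impulses[responsive, f] += config.evoked_amplitude * gains * jitter

    kernel = _calcium_kernel(config)
    traces = signal.fftconvolve(impulses, kernel[None, :], mode="full", axes=1)[
        :, :n_frames
    ]
    if config.noise_sd > 0:
        traces = traces + rng_noise.normal(0.0, config.noise_sd, size=traces.shape)

    gt = GroundTruth(
        sa_assembly_membership=assemblies,
        ea_ensemble_membership=ensembles,
        ensemble_position_deg=thetas,
        true_preferred_deg=pref,
        responsive_neurons=responsive,
        true_event_times=event_times,
    )
    return SyntheticDataset(
        traces=traces,
        positions=positions,
        neuropil_contour=contour,
        stimulus_log=log,
        frame_rate_hz=fps,
        sa_end_frame=sa_end,
        ground_truth=gt,
        config=config,
    )


# ---------------------------------------------------------------------------
# pixel-level movie synthesis
# ---------------------------------------------------------------------------


def generate_movie(
    dataset: SyntheticDataset,
    fov: tuple = (96, 96),
    cell_radius_px: int = 3,
    psf_sigma_px: float = 1.0,
    photon_noise_scale: float = 1.0,
    seed: int = 0,
    scale_um_per_px: Optional[float] = None,
    baseline: float = 100.0,
    amplitude_scale: float = 80.0,
    cell_baseline_contrast: float = 30.0,
    n_frames: Optional[int] = None,
    neuron_indices: Optional[Sequence[int]] = None,
    max_overlap_fraction: float = 0.25,
    min_separation_px: Optional[float] = None,
):
    """Render a pixel-level movie of (a subset of) a dataset.

    Pixel fluorescence inside each disk ROI is ``baseline +
    cell_baseline_contrast + amplitude_scale * trace`` (the contrast term is
    the indicator's resting fluorescence, which is what rigid registration
    locks onto); frames are blurred with a Gaussian PSF and corrupted with
    signal-dependent (sqrt-scaled) noise.  Returns ``(movie, roi_masks)``
    where ``movie`` is float64 of shape (frames, H, W) and ``roi_masks`` is a
    list of per-neuron boolean masks (the ground truth for cell detection).
    """
    h, w = fov
    idx = np.arange(dataset.n_neurons) if neuron_indices is None else np.asarray(neuron_indices)
    traces = dataset.traces[idx]
    if n_frames is not None:
        traces = traces[:, :n_frames]
    pos = dataset.positions[idx]
    if scale_um_per_px is None:
        # spread the field of view to fit all requested neurons
        span = max(np.ptp(pos[:, 0]), np.ptp(pos[:, 1]), 1e-9)
        scale_um_per_px = span / (min(h, w) - 4 * cell_radius_px)
    px = pos / scale_um_per_px
    px -= px.min(axis=0) - 2 * cell_radius_px  # margin
    if (px[:, 0] > w - cell_radius_px - 1).any() or (px[:, 1] > h - cell_radius_px - 1).any():
        raise ValueError("neuron positions do not fit inside the field of view")
    if min_separation_px is not None:
        # deterministic pairwise relaxation so rendered somata do not collide
        for _ in range(200):
            moved = False
            for i in range(len(px)):
                for j in range(i + 1, len(px)):
                    d = px[j] - px[i]
                    dist = float(np.hypot(*d))
                    if dist < min_separation_px:
                        step = (d / dist if dist > 1e-9 else np.array([1.0, 0.0]))
                        push = 0.5 * (min_separation_px - dist) + 0.1
                        px[i] -= step * push
                        px[j] += step * push
                        moved = True
            np.clip(px[:, 0], cell_radius_px + 1, w - cell_radius_px - 2, out=px[:, 0])
            np.clip(px[:, 1], cell_radius_px + 1, h - cell_radius_px - 2, out=px[:, 1])
            if not moved:
                break

    yy, xx = np.mgrid[0:h, 0:w]
    masks = []
    for cx, cy in px:
        masks.append((yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius_px ** 2)
    claimed = np.sum(masks, axis=0)
    overlap_frac = float((claimed > 1).sum() / max((claimed > 0).sum(), 1))
    if overlap_frac > max_overlap_fraction:
        warnings.warn(
            f"{overlap_frac:.0%} of ROI pixels are claimed by more than one "
            "neuron; detection quality will degrade",
            stacklevel=2,
        )

    t_frames = traces.shape[1]
    movie = np.full((t_frames, h, w), float(baseline))
    for m, tr in zip(masks, traces):
        r, c = np.nonzero(m)
        movie[:, r, c] += cell_baseline_contrast + amplitude_scale * tr[:, None]
    if psf_sigma_px > 0:
        movie = ndimage.gaussian_filter(movie, sigma=(0.0, psf_sigma_px, psf_sigma_px))
    if photon_noise_scale > 0:
        rng = np.random.default_rng(seed)
        movie = movie + rng.normal(size=movie.shape) * photon_noise_scale * np.sqrt(
            np.clip(movie, 0.0, None)
        )
    return movie, masks
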