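"""End-to-end orchestration: synthetic data -> metrics report.

Runs all analysis stages in dependency order on a (simulated or loaded)
recording and collects the per-fish metric tables behind each analysis:
distance-binned correlation profiles and correlation-matrix similarity,
the tuning table, assembly statistics and overlap, coactivity levels, PCA
dimensionality per epoch, cross-epoch cosine similarities, and the balanced
subspace-projection fractions.  Identical config + seed reproduces every
numeric output bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, assemblies, correlations, pattern_geometry, tuning
from .preprocessing import EPOCH_EA, EPOCH_SA, EPOCH_SE, binarize, segment_epochs
from .synthetic import SimulationConfig, SyntheticDataset, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "report_to_json"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One config drives every stage; the seed feeds each stochastic step."""

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    out_dir: Optional[str] = None
    corr_n_shuffles: int = 1000
    assembly_n_shuffles: int = 500
    assembly_min_size: int = 5
    coactivity_n_shuffles: int = 500
    alpha: float = 0.05
    distance_bin_um: float = 50.0
    variance_fraction: float = 0.8
    n_select: Optional[int] = None
    n_repeats: int = 200
    match_sa_length: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulate", {}))
        return cls(simulate=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"] = self.simulate.to_dict()
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where results land does not change them
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _json_safe(obj.tolist())
    return obj


def report_to_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_json_safe(report), indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig, dataset: Optional[SyntheticDataset] = None) -> dict:
    """Execute all stages and return the metrics report (dict).

    A pre-built dataset may be supplied; otherwise one is generated from the
    config's simulate block with the pipeline seed.  When ``out_dir`` is set,
    the report JSON and per-stage CSV tables are written there.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(6)]
    s_corr_sa, s_corr_tea, s_asm_sa, s_asm_tea, s_coact, s_geom = seeds

    if dataset is None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        logger.info("simulating dataset (seed=%d)", config.seed)
        dataset = generate_dataset(sim)

    dff = dataset.traces
    logger.info("preprocessing: binarize + epoch segmentation")
    raster = binarize(dff)
    labels = segment_epochs(
        dataset.stimulus_log, dataset.frame_rate_hz, dataset.n_frames,
        dataset.sa_end_frame,
    )
    sa_frames = labels.frames(EPOCH_SA)
    tea_frames = labels.tea_frames()

    # correlations ---------------------------------------------------------
    logger.info("correlations: SHIFT null on SA and TEA")
    corr = {}
    for epoch, frames, cseed in (
        ("SA", sa_frames, s_corr_sa),
        ("TEA", tea_frames, s_corr_tea),
    ):
        corr[epoch] = correlations.shift_null_mask(
            dff, frames, n_shuffles=config.corr_n_shuffles, seed=cseed,
            alpha=config.alpha, epoch=epoch,
        )
    max_d = float(
        np.linalg.norm(np.ptp(dataset.positions, axis=0))
    )
    edges = np.arange(0.0, max_d + config.distance_bin_um, config.distance_bin_um)
    profiles = {
        e: correlations.distance_binned_profile(corr[e], dataset.positions, edges)
        for e in corr
    }
    matrix_sim = correlations.matrix_similarity(corr["SA"], corr["TEA"])

    # tuning ---------------------------------------------------------------
    logger.info("tuning: response amplitudes + Gaussian fits")
    amp_table = tuning.stimulus_response_amplitudes(dff, dataset.stimulus_log)
    tuning_table = tuning.fit_all_neurons(amp_table)

    # assemblies -----------------------------------------------------------
    logger.info("assemblies: detection + statistics")
    ap_axis = assemblies.fit_ap_axis(dataset.neuropil_contour)
    asm = {}
    for epoch, frames, aseed in (
        ("SA", sa_frames, s_asm_sa),
        ("TEA", tea_frames, s_asm_tea),
    ):
        found = assemblies.detect_assemblies(
            raster, frames, epoch=epoch, min_size=config.assembly_min_size,
            n_shuffles=config.assembly_n_shuffles, seed=aseed, alpha=config.alpha,
        )
        for a in found:
            assemblies.assembly_statistics(a, dataset.positions, ap_axis, tuning_table)
        asm[epoch] = found
    overlap = assemblies.assembly_overlap(asm["TEA"], asm["SA"])

    # patterns and geometry ------------------------------------------------
    logger.info("patterns: coactivity threshold + selection")
    pat_labels = labels
    if config.match_sa_length:
        # control: truncate SA to the EA frame count before pattern selection
        n_ea = len(labels.frames(EPOCH_EA))
        keep_sa = labels.frames(EPOCH_SA)[-n_ea:] if n_ea else labels.frames(EPOCH_SA)
        lab = labels.labels.copy()
        drop = np.setdiff1d(labels.frames(EPOCH_SA), keep_sa)
        lab[drop] = "none"
        pat_labels = dataclasses.replace(labels, labels=lab)
    series = pattern_geometry.coactivity_threshold(
        raster, n_shuffles=config.coactivity_n_shuffles, alpha=config.alpha,
        seed=s_coact,
    )
    pattern_sets = pattern_geometry.select_patterns(series, raster, pat_labels)
    coactivity_means = pattern_geometry.mean_coactivity(series, pattern_sets)

    k80 = {}
    for epoch in (EPOCH_EA, EPOCH_SA, EPOCH_SE):
        frames = pat_labels.frames(epoch)
        k80[epoch] = (
            pattern_geometry.pca_dimensionality(dff, frames, config.variance_fraction)
            if len(frames) >= 2
            else None
        )

    cosine = {}
    for a, b in (("EA", "SA"), ("EA", "SE"), ("SA", "SE")):
        try:
            cosine[f"{a}-{b}"] = pattern_geometry.epoch_cosine_similarity(
                pattern_sets[a], pattern_sets[b]
            )
        except ValueError:
            cosine[f"{a}-{b}"] = np.nan

    geometry_pairs, geometry_summary = None, None
    try:
        geometry_pairs, geometry_summary = pattern_geometry.balanced_projection_analysis(
            pattern_sets, n_select=config.n_select, n_repeats=config.n_repeats,
            seed=s_geom,
        )
    except ValueError as exc:
        logger.warning("projection geometry skipped: %s", exc)

    report = {
        "software_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_neurons": dataset.n_neurons,
        "n_frames": dataset.n_frames,
        "n_presentations": len(dataset.stimulus_log),
        "epoch_frame_counts": labels.counts(),
        "correlations": {
            "significant_fraction": {e: corr[e].significant_fraction() for e in corr},
            "null_cutoff": {e: corr[e].null_percentile_value for e in corr},
            "distance_profile": {
                e: profiles[e].to_dict(orient="list") for e in profiles
            },
            "matrix_similarity_sa_tea": matrix_sim,
        },
        "tuning": {
            "n_selective": int(tuning_table["selective"].sum()),
            "selective_fraction": float(tuning_table["selective"].mean()),
        },
        "assemblies": {
            "n_sa": len(asm["SA"]),
            "n_tea": len(asm["TEA"]),
            "mean_size": {
                e: (float(np.mean([a.size for a in asm[e]])) if asm[e] else None)
                for e in asm
            },
            "mean_com_ap": {
                e: (float(np.nanmean([a.com_ap for a in asm[e]])) if asm[e] else None)
                for e in asm
            },
            "tea_sa_overlap": overlap,
        },
        "patterns": {
            "coactivity_threshold": series.threshold,
            "n_patterns": {e: len(ps) for e, ps in pattern_sets.items()},
            "mean_coactivity": coactivity_means,
            "k80": k80,
        },
        "geometry": {
            "cosine_similarity": cosine,
            "unexplained": geometry_summary,
            "pairs": None
            if geometry_pairs is None
            else geometry_pairs.to_dict(orient="list"),
        },
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report_to_json(report, out / "report.json")
        tuning_table.to_csv(out / "tuning.csv")
        assemblies.assembly_table(asm["SA"] + asm["TEA"]).to_csv(
            out / "assemblies.csv", index=False
        )
        pd.concat(
            [profiles[e].assign(epoch=e) for e in profiles], ignore_index=True
        ).to_csv(out / "correlation_profile.csv", index=False)
        if geometry_pairs is not None:
            geometry_pairs.to_csv(out / "geometry.csv", index=False)
        pd.DataFrame(
            {
                "frame": np.concatenate([ps.frames for ps in pattern_sets.values()])
                if pattern_sets else [],
                "epoch": sum(([e] * len(ps) for e, ps in pattern_sets.items()), []),
            }
        ).to_csv(out / "pattern_frames.csv", index=False)
    return report
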