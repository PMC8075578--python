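"""Shared fixtures: small synthetic recordings reused across test modules."""

import numpy as np
import pytest

import tectodyn as td
from tectodyn.preprocessing import binarize, segment_epochs


@pytest.fixture(scope="session")
def small_dataset():
    """A modest recording with default assembly/ensemble structure."""
    cfg = td.SimulationConfig(n_neurons=60, sa_duration_s=400.0, n_trials=5, seed=7)
    return td.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_raster_labels(small_dataset):
    ds = small_dataset
    raster = binarize(ds.traces)
    labels = segment_epochs(
        ds.stimulus_log, ds.frame_rate_hz, ds.n_frames, ds.sa_end_frame
    )
    return raster, labels


@pytest.fixture(scope="session")
def detection_movie():
    """Pixel-level movie with independently active, well-separated cells."""
    cfg = td.SimulationConfig(
        n_neurons=30, n_sa_assemblies=30, sa_assembly_size=1,
        n_ea_ensembles=9, ea_ensemble_size=1, ea_sa_overlap=1.0,
        retinotopy_noise_deg=35.0, sa_duration_s=300.0, n_trials=1,
        assembly_event_rate_hz=0.08, seed=3,
    )
    ds = td.generate_dataset(cfg)
    movie, masks = td.generate_movie(
        ds, fov=(160, 160), cell_radius_px=4, psf_sigma_px=0.8,
        n_frames=500, min_separation_px=11, seed=3,
    )
    return ds, movie, masks
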