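import numpy as np
import pytest

from cellmig import synthetic as syn


@pytest.fixture(scope="session")
def texture_frame():
    """A single noiseless textured frame with no wound (for PIV tests)."""
    cfg = syn.MovieSimConfig(wound_fraction=0.0, n_frames=2, noise_sd=0.0, seed=2)
    return syn.gen_movie(cfg).frames[0].astype(float)


@pytest.fixture(scope="session")
def wound_movie():
    """Synthetic wound-healing movie with an exponential velocity profile."""
    cfg = syn.MovieSimConfig(
        height_px=256, width_px=256, n_frames=10, noise_sd=40.0,
        wound_fraction=0.3, seed=11,
        field_spec=syn.FieldSpec(v0_umh=8.9, lambda_um=40.0),
    )
    return syn.gen_movie(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """60 persistent-random-walk tracks at the tracking-assay scale."""
    cfg = syn.TrackSimConfig(n_cells=60, duration_min=390, dt_min=10,
                             tau_min=60, bias=0.0, seed=1)
    tracks, truth = syn.gen_tracks(cfg)
    return tracks, truth
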