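"""Shared fixtures: all test data is generated programmatically."""
import numpy as np
import pytest

from cardiosync.features import spectral_flux
from cardiosync.synth import (
    default_audience_specs,
    default_stimulus_spec,
    generate_audience,
    generate_stimulus,
)


@pytest.fixture(scope="session")
def stimulus_120s():
    """One 120-s synthetic piece with 5 sections, rendered, with flux."""
    spec = default_stimulus_spec("piece1", seed=5, duration_s=120.0, n_sections=5)
    wave, annotations = generate_stimulus(spec)
    flux = spectral_flux(wave, spec.sample_rate_hz)
    return {"spec": spec, "wave": wave, "annotations": annotations, "flux": flux}


@pytest.fixture(scope="session")
def coupled_audience(stimulus_120s):
    """Four participants coupled to the stimulus (600 ms lag), no orienting."""
    specs = default_audience_specs(
        11, n_concerts=1, n_per_concert=4, orienting_depth_bpm=0.0
    )
    records, manifest = generate_audience(
        120.0,
        specs,
        "AO",
        flux_20hz=stimulus_120s["flux"].flux_20hz,
    )
    return {"records": records, "manifest": manifest, "specs": specs}


@pytest.fixture(scope="session")
def quiet_audience():
    """Independent participants: no stimulus coupling, no orienting."""
    specs = default_audience_specs(
        23, n_concerts=1, n_per_concert=4, coupling_gain=0.0, orienting_depth_bpm=0.0
    )
    records, _ = generate_audience(120.0, specs, "AO")
    return records
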