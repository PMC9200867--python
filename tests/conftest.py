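"""Shared fixtures: noise-free preset records and averaged beats."""

from dataclasses import replace

import numpy as np
import pytest

from vcgdi import (
    PRESETS,
    PipelineConfig,
    average_beats,
    detect_peaks,
    extract_windows,
    generate_record,
    kors_transform,
)
from vcgdi.preprocessing import bandpass_filter, remove_baseline

PRESET_NAMES = ("normal", "rbbb", "lbbb", "paced")


def clean_params(name):
    """Preset parameters with all disturbances switched off."""
    return replace(PRESETS[name], noise_sd_mv=0.0, drift_amp_mv=0.0,
                   powerline_amp_mv=0.0, heart_rate_bpm=60.0)


def make_clean_record(name):
    record, truth = generate_record(clean_params(name), patient_id=name)
    return record, truth


def average_beat_from_record(record, preprocess=True):
    """Run the signal chain up to the averaged beat."""
    rec = record
    if preprocess:
        rec = remove_baseline(bandpass_filter(rec))
    vcg = kors_transform(rec)
    peaks = detect_peaks(vcg.voltage, vcg.sampling_rate)
    ensemble = extract_windows(vcg, peaks)
    return average_beats(ensemble)


@pytest.fixture(scope="session")
def clean_records():
    """Noise-free record + ground truth for every preset."""
    return {name: make_clean_record(name) for name in PRESET_NAMES}


@pytest.fixture(scope="session")
def clean_average_beats(clean_records):
    return {name: average_beat_from_record(rec)
            for name, (rec, _) in clean_records.items()}


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
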