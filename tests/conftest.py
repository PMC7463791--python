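"""Shared fixtures: tiny hand-built datasets and one full-scale pipeline run.

The full-scale run (the default simulated study: 2x4 patients, ~2300
tissue spectra, 200 peaks, 20 discriminative) is session-scoped so the
end-to-end checks share a single computation.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from msimarkers import MSIDataset, ROI, ROISet, Spectrum
from msimarkers.pipeline import PipelineConfig, run_pipeline
from msimarkers.synthetic import SimConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def gaussian(axis, center, height, sigma):
    return height * np.exp(-((axis - center) ** 2) / (2 * sigma**2))


@pytest.fixture
def grid3x3():
    """3x3 continuous-mode dataset with a shared axis."""
    axis = np.arange(800.0, 1000.0, 0.5)
    rng = np.random.default_rng(7)
    spectra = [
        Spectrum(axis, rng.uniform(0, 10, axis.size), (x, y))
        for x in (1, 2, 3)
        for y in (1, 2, 3)
    ]
    return MSIDataset(spectra, mass_range=(800.0, 1000.0))


@pytest.fixture
def two_group_rois():
    """Two single-pixel ROIs per group plus one control pixel."""
    return ROISet(
        [
            ROI("a1", "A", "+RD", frozenset({(1, 1), (2, 1)})),
            ROI("b1", "B", "-RD", frozenset({(1, 2), (2, 2)})),
            ROI("ctrl", "CTRL", "control", frozenset({(3, 3)})),
        ]
    )


@pytest.fixture
def small_sim_config():
    """Fast, small simulation used by unit tests."""
    return SimConfig(
        n_patients_per_group=2,
        cores_per_patient=1,
        spots_per_core=36,
        mass_range=(800.0, 1400.0),
        n_peaks=40,
        n_discriminative=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the default study scale (seeded)."""
    return run_pipeline(PipelineConfig(), seed=1)
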