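"""Spectrum preprocessing: baseline removal and TIC normalization.

Both operations are applied uniformly to every spectrum of a dataset before
any statistics, so that per-pixel ionization-efficiency differences and the
slowly varying chemical background (matrix clusters, detector drift) do not
masquerade as biology.

Baseline removal is a convolution-style morphological estimate: a moving
minimum of window ``width`` samples followed by a moving average of the same
window.  The moving minimum tracks the slowly varying floor underneath the
peaks; the smoothing step removes the staircase artefacts of the minimum
filter.  The estimate is subtracted and negative residuals are clipped to
zero.  With the default width of 20 samples, peaks a few samples wide pass
through essentially unchanged while any structure wider than the window is
treated as background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d

from .errors import NormalizationError, ParameterError
from .io_msi import MSIDataset, Spectrum


@dataclass
class PreprocessParams:
    """Preprocessing settings: window width in samples and a normalize flag."""

    baseline_width: int = 20
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.baseline_width < 3:
            raise ParameterError("baseline_width must be >= 3")


def baseline_estimate(intensity: np.ndarray, width: int) -> np.ndarray:
    """Moving-minimum + moving-average baseline of a 1-D (or row-wise 2-D) signal."""
    if width < 3:
        raise ParameterError("width must be >= 3")
    if intensity.shape[-1] < width:
        raise ParameterError(
            f"width {width} exceeds spectrum length {intensity.shape[-1]}"
        )
    floor = minimum_filter1d(intensity, size=width, axis=-1, mode="nearest")
    return uniform_filter1d(floor, size=width, axis=-1, mode="nearest")


def remove_baseline(s: Spectrum, width: int = 20) -> Spectrum:
    """Return a new spectrum with the baseline estimate subtracted.

    Negative residuals are clipped to zero; the m/z axis is unchanged.
    """
    corrected = s.intensity - baseline_estimate(s.intensity, width)
    np.clip(corrected, 0.0, None, out=corrected)
    return Spectrum(s.mz, corrected, s.coord, s.region_id)


def tic_normalize(s: Spectrum) -> Spectrum:
    """Scale intensities to unit total ion count (sum of intensities = 1)."""
    total = float(s.intensity.sum())
    if total <= 0:
        raise NormalizationError(f"spectrum at {s.coord} has zero total ion count")
    return Spectrum(s.mz, s.intensity / total, s.coord, s.region_id)


def preprocess_dataset(ds: MSIDataset, params: PreprocessParams | None = None) -> MSIDataset:
    """Baseline-correct (and optionally TIC-normalize) every spectrum.

    Spectra whose total ion count is zero after baseline removal (possible
    for off-tissue control pixels) are left unnormalized rather than
    rejected, so control regions survive preprocessing.
    """
    params = params or PreprocessParams()
    out = []
    for s in ds:
        t = remove_baseline(s, params.baseline_width)
        if params.normalize:
            try:
                t = tic_normalize(t)
            except NormalizationError:
                pass
        out.append(t)
    return MSIDataset(out, raster_um=ds.raster_um, mass_range=ds.mass_range, meta=dict(ds.meta))
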