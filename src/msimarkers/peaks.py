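"""Peak picking on the dataset mean spectrum and feature-matrix construction.

Peak picking runs orthogonal matching pursuit (OMP) against a dictionary of
Gaussian peak templates centred at every point of a uniform m/z axis: at
each iteration the template most correlated with the current residual is
added to the model, the coefficients of *all* selected templates are re-fit
by least squares, and the residual is updated.  Selection stops when the
requested number of peaks is reached or the best residual correlation drops
below a threshold (by default a robust noise-floor estimate).  Because the
dictionary is shift-invariant, the correlation of the residual with every
template is a single Gaussian filtering pass, making each iteration O(n).

Picked peaks become intensity bins of fixed half-width (default +/-0.156 Da)
and each analyzed spectrum is summarized by its mean intensity inside each
bin, yielding the spectra x bins feature matrix every downstream statistic
consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve
from scipy.ndimage import correlate1d

from .errors import EmptyDataError, ParameterError
from .io_msi import MSIDataset, ROISet, Spectrum

logger = logging.getLogger(__name__)

DEFAULT_AXIS_STEP_DA = 0.05
DEFAULT_HALF_WIDTH_DA = 0.156


@dataclass
class PeakList:
    """Picked peak centroids (Da, ascending) and OMP diagnostics."""

    centers: np.ndarray
    threshold: float
    selection_order: np.ndarray = field(default_factory=lambda: np.empty(0))
    residual_norms: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if len(self.centers) > 1 and not np.all(np.diff(self.centers) > 0):
            raise ValueError("peak centers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class FeatureMatrix:
    """Spectra x binned-m/z intensity table with per-row spot metadata.

    ``spot_index`` is a DataFrame aligned with the rows of ``values`` and
    carries columns ``x, y, roi, patient, group``.
    """

    values: np.ndarray
    bin_centers: np.ndarray
    half_width: float
    spot_index: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.bin_centers = np.asarray(self.bin_centers, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (spectra x bins)")
        if self.values.shape[1] != len(self.bin_centers):
            raise ValueError("one bin center per column required")
        if self.values.shape[0] != len(self.spot_index):
            raise ValueError("one spot_index row per spectrum required")
        if np.any(self.values < 0):
            raise ValueError("feature matrix entries must be non-negative")
        if len(self.bin_centers) > 1 and not np.all(np.diff(self.bin_centers) > 0):
            raise ValueError("bin centers must be strictly increasing")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    def group_rows(self, group: str) -> np.ndarray:
        return np.flatnonzero((self.spot_index["group"] == group).to_numpy())

    def subset_rows(self, rows) -> "FeatureMatrix":
        rows = np.asarray(rows)
        return FeatureMatrix(
            self.values[rows],
            self.bin_centers,
            self.half_width,
            self.spot_index.iloc[rows].reset_index(drop=True),
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=[f"{c:.4f}" for c in self.bin_centers])
        pd.concat([self.spot_index.reset_index(drop=True), df], axis=1).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# Mean spectrum
# ---------------------------------------------------------------------------

def mean_spectrum(
    ds: MSIDataset,
    rois: ROISet | None = None,
    step: float = DEFAULT_AXIS_STEP_DA,
) -> Spectrum:
    """Arithmetic mean of the selected spectra on a common uniform axis.

    If ``rois`` is given, only pixels inside its tissue (non-control) ROIs
    contribute.  Per-pixel axes are linearly interpolated onto the common
    axis (zero outside each spectrum's own range).
    """
    if rois is not None:
        wanted = {c for roi in rois.tissue_rois() for c in roi.coords}
        spectra = [s for s in ds if s.coord in wanted]
    else:
        spectra = list(ds)
    if not spectra:
        raise EmptyDataError("no spectra selected for the mean spectrum")
    lo, hi = ds.mass_range
    axis = np.arange(lo, hi + step / 2, step)
    acc = np.zeros_like(axis)
    for s in spectra:
        acc += np.interp(axis, s.mz, s.intensity, left=0.0, right=0.0)
    acc /= len(spectra)
    return Spectrum(axis, acc, (0, 0), region_id="mean")


def _require_uniform(mz: np.ndarray) -> float:
    steps = np.diff(mz)
    if len(steps) == 0:
        raise ParameterError("spectrum too short")
    step = steps[0]
    if not np.allclose(steps, step, rtol=1e-6, atol=1e-9):
        raise ParameterError("peak picking requires a uniform m/z axis")
    return float(step)


# ---------------------------------------------------------------------------
# Orthogonal matching pursuit
# ---------------------------------------------------------------------------

def pick_peaks_omp(
    mean: Spectrum,
    max_peaks: int = 300,
    threshold: float | None = None,
    sigma_da: float | None = None,
) -> PeakList:
    """Greedy OMP peak picking on a uniform-axis mean spectrum.

    Parameters
    ----------
    max_peaks:
        Hard cap on the number of selected templates.
    threshold:
        Stop when the best residual correlation (inner product of the
        residual with a unit-norm Gaussian template) falls below this score.
        ``None`` estimates a noise floor as five times the robust (MAD)
        scale of the correlation signal of the input.
    sigma_da:
        Gaussian template width; default two axis steps.
    """
    step = _require_uniform(mean.mz)
    sigma = 2 * step if sigma_da is None else float(sigma_da)
    if sigma <= 0:
        raise ParameterError("sigma_da must be positive")
    y = mean.intensity.astype(np.float64)
    n = len(y)

    half = max(1, int(round(4 * sigma / step)))
    t = np.arange(-half, half + 1) * step
    kernel = np.exp(-(t**2) / (2 * sigma**2))
    kernel /= np.linalg.norm(kernel)

    corr = correlate1d(y, kernel, mode="constant", cval=0.0)
    if threshold is None:
        med = np.median(corr)
        mad = np.median(np.abs(corr - med))
        threshold = float(5 * 1.4826 * mad)
    residual = y.copy()
    selected: list[int] = []
    A = np.zeros((n, max_peaks))           # selected atoms, preallocated
    G = np.eye(max_peaks)                  # Gram matrix of selected atoms
    rhs = np.zeros(max_peaks)
    norms = [float(np.linalg.norm(residual))]

    while len(selected) < max_peaks:
        corr = correlate1d(residual, kernel, mode="constant", cval=0.0)
        corr[selected] = -np.inf  # never reselect a center
        j = int(np.argmax(corr))
        score = float(corr[j])
        if score < threshold:
            break
        a, b = max(0, j - half), min(n, j + half + 1)
        ka = a - (j - half)
        k = len(selected)
        A[a:b, k] = kernel[ka:ka + (b - a)]
        cross = A[:, :k].T @ A[:, k]
        G[:k, k] = cross
        G[k, :k] = cross
        G[k, k] = float(A[:, k] @ A[:, k])
        rhs[k] = float(A[:, k] @ y)
        selected.append(j)
        k += 1
        coef = solve(
            G[:k, :k] + 1e-12 * np.eye(k), rhs[:k], assume_a="pos"
        )
        residual = y - A[:, :k] @ coef
        norms.append(float(np.linalg.norm(residual)))

    order = np.asarray([mean.mz[j] for j in selected])
    centers = np.unique(order)
    return PeakList(
        centers=centers,
        threshold=float(threshold),
        selection_order=order,
        residual_norms=np.asarray(norms),
    )


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

def _merge_overlapping(centers: np.ndarray, half_width: float) -> np.ndarray:
    """Merge centers whose bins would overlap (separation <= 2*half_width)."""
    merged = [float(centers[0])]
    counts = [1]
    for c in centers[1:]:
        if c - merged[-1] <= 2 * half_width:
            # running mean of the merged cluster
            counts[-1] += 1
            merged[-1] += (c - merged[-1]) / counts[-1]
        else:
            merged.append(float(c))
            counts.append(1)
    if len(merged) < len(centers):
        warnings.warn(
            f"merged {len(centers) - len(merged)} overlapping peak bin(s) "
            f"(separation <= {2 * half_width:.3f} Da)",
            stacklevel=3,
        )
    return np.asarray(merged)


def build_feature_matrix(
    ds: MSIDataset,
    rois: ROISet,
    peaks: PeakList,
    half_width: float = DEFAULT_HALF_WIDTH_DA,
) -> FeatureMatrix:
    """Mean intensity of every tissue spectrum inside every peak bin.

    Entry (i, j) is the mean of spectrum i's samples with m/z in the closed
    interval ``[center_j - half_width, center_j + half_width]``.  Bins with
    no samples yield 0 (logged once).  Control ROIs are excluded.
    """
    if len(peaks) == 0:
        raise EmptyDataError("peak list is empty")
    if half_width <= 0:
        raise ParameterError("half_width must be positive")
    centers = _merge_overlapping(peaks.centers, half_width)

    coord_map = {c: roi for roi in rois.tissue_rois() for c in roi.coords}
    rows = []
    meta = []
    empty_bins = False
    lows = centers - half_width
    highs = centers + half_width
    for s in ds:
        roi = coord_map.get(s.coord)
        if roi is None:
            continue
        lo_idx = np.searchsorted(s.mz, lows, side="left")
        hi_idx = np.searchsorted(s.mz, highs, side="right")
        cs = np.concatenate([[0.0], np.cumsum(s.intensity)])
        counts = hi_idx - lo_idx
        sums = cs[hi_idx] - cs[lo_idx]
        if np.any(counts == 0):
            empty_bins = True
        vals = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        rows.append(vals)
        meta.append((s.coord[0], s.coord[1], roi.name, roi.patient_id, roi.group))
    if not rows:
        raise EmptyDataError("no spectra fall inside the tissue ROIs")
    if empty_bins:
        logger.warning("some peak bins contained no m/z samples; set to 0")
    spot_index = pd.DataFrame(meta, columns=["x", "y", "roi", "patient", "group"])
    return FeatureMatrix(np.asarray(rows), centers, half_width, spot_index)
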