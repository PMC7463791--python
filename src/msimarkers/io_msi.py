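"""Domain containers and file I/O for imaging mass-spectrometry data.

The in-memory model is deliberately simple: an :class:`MSIDataset` is an
ordered collection of per-pixel :class:`Spectrum` objects, each carrying its
own m/z axis (so both continuous-mode data, where every pixel shares one
axis, and processed-mode data, where axes differ per pixel, fit the same
model).  Regions of interest (tissue cores with patient and outcome-group
labels, plus off-tissue control areas) live in a separate :class:`ROISet`
keyed by 1-based pixel coordinates, matching the imzML convention.

On disk, datasets are exchanged as imzML + ibd pairs (via ``pyimzml``),
everything tabular (ROI masks, reference peptide lists, marker and
annotation tables) as plain CSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyDataError, FormatError, ParseError, SchemaError

GROUP_POSITIVE = "+RD"
GROUP_NEGATIVE = "-RD"
GROUP_CONTROL = "control"
VALID_GROUPS = (GROUP_POSITIVE, GROUP_NEGATIVE, GROUP_CONTROL)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """One pixel's mass spectrum.

    Parameters
    ----------
    mz:
        Mass-to-charge values in Da, strictly increasing.
    intensity:
        Non-negative abundances (arbitrary units), same length as ``mz``.
    coord:
        1-based integer ``(x, y)`` grid position of the pixel.
    region_id:
        Optional label of the ROI the pixel belongs to.
    """

    mz: np.ndarray
    intensity: np.ndarray
    coord: tuple[int, int]
    region_id: str | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if len(self.mz) != len(self.intensity):
            raise ValueError(
                f"length mismatch: {len(self.mz)} m/z vs {len(self.intensity)} intensities"
            )
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        self.coord = (int(self.coord[0]), int(self.coord[1]))

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class MSIDataset:
    """An imaging-MS dataset: one spectrum per pixel plus acquisition metadata.

    ``mass_range`` is the instrument detection window in Da; all spectra must
    lie within it.  ``raster_um`` is the pixel pitch in micrometres.
    """

    spectra: list[Spectrum]
    raster_um: float = 50.0
    mass_range: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        coords = [s.coord for s in self.spectra]
        if len(set(coords)) != len(coords):
            seen, dup = set(), None
            for c in coords:
                if c in seen:
                    dup = c
                    break
                seen.add(c)
            raise ValueError(f"duplicate pixel coordinate {dup}")
        if self.mass_range is None and self.spectra:
            lo = min(float(s.mz[0]) for s in self.spectra if len(s))
            hi = max(float(s.mz[-1]) for s in self.spectra if len(s))
            self.mass_range = (lo, hi)
        if self.mass_range is not None:
            lo, hi = self.mass_range
            for s in self.spectra:
                if len(s) and (s.mz[0] < lo - 1e-9 or s.mz[-1] > hi + 1e-9):
                    raise ValueError(
                        f"spectrum at {s.coord} exceeds mass_range {self.mass_range}"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def coords(self) -> list[tuple[int, int]]:
        return [s.coord for s in self.spectra]

    def subset(self, coords) -> "MSIDataset":
        """Restrict to the given coordinates (order of the dataset preserved)."""
        wanted = set(coords)
        return MSIDataset(
            [s for s in self.spectra if s.coord in wanted],
            raster_um=self.raster_um,
            mass_range=self.mass_range,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class ROI:
    """A named region of interest: one tissue core (or off-tissue control)."""

    name: str
    patient_id: str
    group: str
    coords: frozenset

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"group must be one of {VALID_GROUPS}, got {self.group!r}")


@dataclass
class ROISet:
    """All ROIs of a dataset; every pixel belongs to at most one ROI."""

    rois: list[ROI]

    def __post_init__(self) -> None:
        seen: dict = {}
        for roi in self.rois:
            for c in roi.coords:
                if c in seen:
                    raise ValueError(
                        f"coordinate {c} assigned to both {seen[c]!r} and {roi.name!r}"
                    )
                seen[c] = roi.name

    def __iter__(self):
        return iter(self.rois)

    def coord_map(self) -> dict:
        """Map coordinate -> ROI."""
        return {c: roi for roi in self.rois for c in roi.coords}

    def tissue_rois(self) -> list[ROI]:
        return [r for r in self.rois if r.group != GROUP_CONTROL]

    def groups(self) -> list[str]:
        return sorted({r.group for r in self.rois})


@dataclass(frozen=True)
class ReferencePeptide:
    """One LC-MS/MS-identified tryptic peptide used for annotation."""

    neutral_mass: float
    accession: str
    protein_name: str = ""
    hgnc: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.neutral_mass > 0:
            raise ValueError("neutral_mass must be positive")
        if not self.accession:
            raise ValueError("accession must be non-empty")


# ---------------------------------------------------------------------------
# imzML I/O
# ---------------------------------------------------------------------------

def write_imzml(dataset: MSIDataset, path: str | os.PathLike, mode: str = "auto") -> None:
    """Write a dataset as an imzML/ibd pair.

    ``mode`` follows pyimzml semantics: ``"auto"`` stores a shared m/z axis
    once (continuous mode) when all spectra share one, otherwise per-pixel
    axes (processed mode).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if len(dataset) == 0:
        raise EmptyDataError("refusing to write an empty dataset")
    with ImzMLWriter(os.fspath(path), mode=mode) as writer:
        for s in dataset:
            writer.addSpectrum(s.mz, s.intensity, coords=(s.coord[0], s.coord[1], 1))


def read_imzml(path: str | os.PathLike) -> MSIDataset:
    """Read an imzML/ibd pair into an :class:`MSIDataset`.

    Coordinates are kept as the file's 1-based grid indices.  Raises
    :class:`FormatError` for missing/corrupt files and
    :class:`EmptyDataError` for files with zero pixels.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        parser = ImzMLParser(path)
    except Exception as exc:  # pyimzml raises assorted low-level errors
        raise FormatError(f"cannot parse imzML file {path}: {exc}") from exc
    try:
        spectra = []
        seen = set()
        for i, (x, y, _z) in enumerate(parser.coordinates):
            if (x, y) in seen:
                raise ValueError(f"duplicate pixel coordinate {(x, y)}")
            seen.add((x, y))
            mz, inten = parser.getspectrum(i)
            spectra.append(Spectrum(np.asarray(mz), np.asarray(inten), (x, y)))
    except ValueError:
        raise
    except Exception as exc:
        raise FormatError(f"corrupt binary data in {path}: {exc}") from exc
    finally:
        m = getattr(parser, "m", None)
        if m is not None:
            m.close()
    if not spectra:
        raise EmptyDataError(f"{path} contains zero pixels")
    return MSIDataset(spectra, meta={"source": path})


def imzml_mode(path: str | os.PathLike) -> str:
    """Return ``"continuous"`` or ``"processed"`` as declared in the imzML XML."""
    text = open(os.fspath(path), encoding="utf-8", errors="replace").read()
    if 'name="continuous"' in text:
        return "continuous"
    if 'name="processed"' in text:
        return "processed"
    raise FormatError(f"{path} declares neither continuous nor processed mode")


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_REF_REQUIRED = ("mass", "accession", "protein", "hgnc")


def read_reference_list(path: str | os.PathLike) -> list[ReferencePeptide]:
    """Read an LC-MS/MS reference peptide list from CSV.

    Required columns: ``mass`` (neutral monoisotopic Mr, Da), ``accession``,
    ``protein``, ``hgnc``.  Optional column: ``score``.  Row order preserved.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _REF_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"reference list is missing column(s): {', '.join(missing)}")
    peptides = []
    for idx, row in df.iterrows():
        try:
            mass = float(row["mass"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"row {idx}: non-numeric mass {row['mass']!r}") from exc
        score = None
        if "score" in df.columns and pd.notna(row.get("score")):
            try:
                score = float(row["score"])
            except (TypeError, ValueError) as exc:
                raise ParseError(f"row {idx}: non-numeric score {row['score']!r}") from exc
        peptides.append(
            ReferencePeptide(
                neutral_mass=mass,
                accession=str(row["accession"]),
                protein_name="" if pd.isna(row["protein"]) else str(row["protein"]),
                hgnc="" if pd.isna(row["hgnc"]) else str(row["hgnc"]),
                score=score,
            )
        )
    return peptides


def write_reference_list(peptides: list[ReferencePeptide], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "mass": [p.neutral_mass for p in peptides],
            "accession": [p.accession for p in peptides],
            "protein": [p.protein_name for p in peptides],
            "hgnc": [p.hgnc for p in peptides],
            "score": [p.score for p in peptides],
        }
    ).to_csv(path, index=False)


def write_rois(rois: ROISet, path: str | os.PathLike) -> None:
    """Write ROI membership as CSV (one row per pixel)."""
    rows = [
        (roi.name, roi.patient_id, roi.group, x, y)
        for roi in rois
        for (x, y) in sorted(roi.coords)
    ]
    pd.DataFrame(rows, columns=["name", "patient_id", "group", "x", "y"]).to_csv(
        path, index=False
    )


def read_rois(path: str | os.PathLike) -> ROISet:
    df = pd.read_csv(path)
    missing = [c for c in ("name", "patient_id", "group", "x", "y") if c not in df.columns]
    if missing:
        raise SchemaError(f"ROI table is missing column(s): {', '.join(missing)}")
    rois = []
    for (name, pid, group), sub in df.groupby(["name", "patient_id", "group"], sort=False):
        coords = frozenset((int(x), int(y)) for x, y in zip(sub["x"], sub["y"]))
        rois.append(ROI(str(name), str(pid), str(group), coords))
    return ROISet(rois)
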