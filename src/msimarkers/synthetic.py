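"""Synthetic imaging-MS data with known ground truth.

The generator emulates a tissue-microarray MALDI-imaging experiment on two
outcome groups of early-stage tumor patients: patients with recurrent
disease (``+RD``) and without (``-RD``).  Each patient contributes a number
of tissue cores; each core is a square block of measurement spots on a
common raster.  Every spot's spectrum is a sum of Gaussian peptide peaks
with log-normal per-spot abundances, a smooth additive baseline, additive
detector noise (truncated at zero) and a multiplicative per-spot total-ion
scale.  A chosen subset of peaks carries a multiplicative group effect in
``+RD`` spots — half of them up-regulated by ``effect_size``, half
down-regulated by ``1/effect_size`` — giving downstream marker discovery a
known answer key.

Off-tissue control cores contain baseline and noise only, mirroring the
control areas measured around a tissue microarray to rule out matrix or
contamination signals.

Defaults are desk-scale: 2x4 patients, 2 cores each, 12x12 spots per core
(~2300 tissue spectra), 200 peaks of which 20 are discriminative, over
m/z 800-3200 at a 50 um raster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigError
from .io_msi import (
    GROUP_CONTROL,
    GROUP_NEGATIVE,
    GROUP_POSITIVE,
    MSIDataset,
    ROI,
    ROISet,
    ReferencePeptide,
    Spectrum,
)

PROTON_LIKE_CARRIER_DA = 1.0079  # charge-carrier mass used for MH+ <-> Mr


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    All intensity-like quantities are in arbitrary units; masses in Da.
    ``tic_cv`` and ``abundance_cv`` are coefficients of variation of
    log-normal multiplicative factors (per spot, and per spot-and-peak).
    """

    n_patients_per_group: int = 4
    cores_per_patient: int = 2
    spots_per_core: int = 144
    mass_range: tuple[float, float] = (800.0, 3200.0)
    n_peaks: int = 200
    n_discriminative: int = 20
    effect_size: float = 4.0
    peak_width_da: float = 0.25
    baseline_amp: float = 2.0
    noise_sd: float = 0.5
    tic_cv: float = 0.25
    abundance_cv: float = 0.4
    axis_step_da: float = 0.1
    raster_um: float = 50.0
    control_cores: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients_per_group", "cores_per_patient", "spots_per_core", "n_peaks"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0 <= self.n_discriminative <= self.n_peaks:
            raise ConfigError("n_discriminative must be between 0 and n_peaks")
        if not self.effect_size > 0:
            raise ConfigError("effect_size must be positive")
        lo, hi = self.mass_range
        if not hi > lo:
            raise ConfigError("mass_range must be increasing")
        # peaks are placed in evenly spaced slots; slots narrower than the
        # peaks themselves would make neighbours unresolvable by construction
        slot = (hi - lo - 20.0) / self.n_peaks
        if slot < 6 * self.peak_width_da:
            raise ConfigError(
                f"{self.n_peaks} peaks of width {self.peak_width_da} Da do not fit "
                f"the mass range {self.mass_range}"
            )

    def to_yaml(self, path) -> None:
        d = self.__dict__.copy()
        d["mass_range"] = list(self.mass_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "mass_range" in d:
            d["mass_range"] = tuple(d["mass_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Answer key of a simulated dataset."""

    peak_mzs: np.ndarray              # all true peak centres (Da), ascending
    discriminative_mask: np.ndarray   # boolean, aligned with peak_mzs
    direction: np.ndarray             # "up"/"down" (in +RD) per discriminative peak
    base_abundance: np.ndarray        # mean abundance per peak (arbitrary units)
    spot_groups: dict = field(default_factory=dict)  # (x, y) -> group label

    @property
    def discriminative_mzs(self) -> np.ndarray:
        return self.peak_mzs[self.discriminative_mask]


def _core_layout(cfg: SimConfig) -> tuple[int, int]:
    """Side length of a square core and number of core columns in the TMA."""
    side = math.ceil(math.sqrt(cfg.spots_per_core))
    n_cores = 2 * cfg.n_patients_per_group * cfg.cores_per_patient + cfg.control_cores
    return side, math.ceil(math.sqrt(n_cores))


def generate_dataset(cfg: SimConfig) -> tuple[MSIDataset, ROISet, GroundTruth]:
    """Simulate one TMA acquisition; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.mass_range
    axis = np.arange(lo, hi + cfg.axis_step_da / 2, cfg.axis_step_da)
    n_axis = len(axis)

    # --- true peak species -------------------------------------------------
    # evenly spaced slots with random jitter keep peaks well separated
    slot = (hi - lo - 20.0) / cfg.n_peaks
    peak_mzs = (
        lo + 10.0 + (np.arange(cfg.n_peaks) + 0.5) * slot
        + rng.uniform(-0.3, 0.3, cfg.n_peaks) * slot
    )
    peak_mzs.sort()
    base_abundance = rng.lognormal(mean=math.log(50.0), sigma=0.8, size=cfg.n_peaks)

    disc_idx = np.sort(rng.choice(cfg.n_peaks, size=cfg.n_discriminative, replace=False))
    mask = np.zeros(cfg.n_peaks, dtype=bool)
    mask[disc_idx] = True
    direction = np.where(np.arange(cfg.n_discriminative) % 2 == 0, "up", "down")
    fold = np.ones(cfg.n_peaks)
    fold[disc_idx] = np.where(direction == "up", cfg.effect_size, 1.0 / cfg.effect_size)

    # --- TMA layout --------------------------------------------------------
    side, core_cols = _core_layout(cfg)
    pitch = side + 2  # 2-pixel gap between cores
    cores = []  # (name, patient, group)
    for gi, group in enumerate((GROUP_POSITIVE, GROUP_NEGATIVE)):
        for p in range(cfg.n_patients_per_group):
            pid = f"P{'pos' if gi == 0 else 'neg'}{p + 1}"
            for c in range(cfg.cores_per_patient):
                cores.append((f"{pid}_core{c + 1}", pid, group))
    for c in range(cfg.control_cores):
        cores.append((f"CTRL_core{c + 1}", "CTRL", GROUP_CONTROL))
    # randomize core placement on the slide, as done for real TMAs
    order = rng.permutation(len(cores))

    sigma_spot = math.sqrt(math.log(1.0 + cfg.abundance_cv**2))
    sigma_tic = math.sqrt(math.log(1.0 + cfg.tic_cv**2)) if cfg.tic_cv > 0 else 0.0
    half_support = max(1, int(round(4 * cfg.peak_width_da / cfg.axis_step_da)))
    t = np.arange(-half_support, half_support + 1) * cfg.axis_step_da
    kernel = np.exp(-(t**2) / (2 * cfg.peak_width_da**2))
    centre_idx = np.clip(np.round((peak_mzs - lo) / cfg.axis_step_da).astype(int), 0, n_axis - 1)

    spectra: list[Spectrum] = []
    rois: list[ROI] = []
    spot_groups: dict = {}
    for slot_i, core_i in enumerate(order):
        name, pid, group = cores[core_i]
        cx = (slot_i % core_cols) * pitch + 1
        cy = (slot_i // core_cols) * pitch + 1
        coords = [
            (cx + j % side, cy + j // side) for j in range(cfg.spots_per_core)
        ]
        n_spots = len(coords)
        tissue = group != GROUP_CONTROL
        if tissue:
            mean_ab = base_abundance * (fold if group == GROUP_POSITIVE else 1.0)
            # log-normal per-spot abundances with unit mean multiplier
            mult = rng.lognormal(
                mean=-sigma_spot**2 / 2, sigma=sigma_spot, size=(n_spots, cfg.n_peaks)
            )
            abundance = mean_ab[None, :] * mult
        else:
            abundance = np.zeros((n_spots, cfg.n_peaks))
        block = np.zeros((n_spots, n_axis))
        for k in range(cfg.n_peaks):
            ci = centre_idx[k]
            a = max(0, ci - half_support)
            b = min(n_axis, ci + half_support + 1)
            ka = a - (ci - half_support)
            block[:, a:b] += abundance[:, k, None] * kernel[None, ka:ka + (b - a)]
        if cfg.baseline_amp > 0:
            phase = rng.uniform(0, 2 * math.pi, size=n_spots)
            period = (hi - lo) / 3.0
            block += cfg.baseline_amp * (
                0.6 + 0.4 * np.sin(2 * math.pi * (axis[None, :] - lo) / period + phase[:, None])
            )
        if sigma_tic > 0:
            scale = rng.lognormal(mean=-sigma_tic**2 / 2, sigma=sigma_tic, size=n_spots)
            block *= scale[:, None]
        if cfg.noise_sd > 0:
            block += rng.normal(0.0, cfg.noise_sd, size=block.shape)
        np.clip(block, 0.0, None, out=block)
        for j, (x, y) in enumerate(coords):
            spectra.append(Spectrum(axis, block[j], (x, y), region_id=name))
            spot_groups[(x, y)] = group
        rois.append(ROI(name, pid, group, frozenset(coords)))

    ds = MSIDataset(
        spectra,
        raster_um=cfg.raster_um,
        mass_range=cfg.mass_range,
        meta={"generator": "msimarkers.synthetic", "seed": cfg.seed},
    )
    truth = GroundTruth(
        peak_mzs=peak_mzs,
        discriminative_mask=mask,
        direction=direction,
        base_abundance=base_abundance,
        spot_groups=spot_groups,
    )
    return ds, ROISet(rois), truth


def generate_reference_list(
    truth: GroundTruth,
    decoys: int = 50,
    mass_jitter_da: float = 0.05,
    seed: int = 0,
    charge_carrier_da: float = PROTON_LIKE_CARRIER_DA,
) -> list[ReferencePeptide]:
    """Emulate the LC-MS/MS identification list for a simulated dataset.

    One entry per true peak at neutral mass ``peak_mz - charge_carrier + jitter``
    with ``jitter ~ N(0, mass_jitter_da^2)``, plus ``decoys`` entries at random
    masses labelled with decoy accessions.  Protein labels are assigned in
    pairs so that proteins owning two or more peptides exist (exercising the
    multi-peptide acceptance rule).
    """
    if mass_jitter_da < 0:
        raise ConfigError("mass_jitter_da must be >= 0")
    rng = np.random.default_rng(seed)
    peptides = []
    for i, mz in enumerate(truth.peak_mzs):
        prot = i // 2  # two peptides per simulated protein
        peptides.append(
            ReferencePeptide(
                neutral_mass=float(mz - charge_carrier_da + rng.normal(0.0, mass_jitter_da)),
                accession=f"SIM{prot:04d}_HUMAN",
                protein_name=f"Simulated protein {prot}",
                hgnc=f"SIM{prot}",
                score=float(rng.uniform(40, 120)),
            )
        )
    if truth.peak_mzs.size:
        lo = float(truth.peak_mzs.min() - charge_carrier_da - 5)
        hi = float(truth.peak_mzs.max() - charge_carrier_da + 5)
    else:
        lo, hi = 800.0, 3200.0
    for d in range(decoys):
        peptides.append(
            ReferencePeptide(
                neutral_mass=float(rng.uniform(lo, hi)),
                accession=f"DECOY{d:04d}",
                protein_name=f"Decoy protein {d}",
                hgnc=f"DEC{d}",
                score=float(rng.uniform(25, 60)),
            )
        )
    return peptides


def is_decoy(accession: str) -> bool:
    """True for reference entries generated as decoys."""
    return accession.startswith("DECOY")
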