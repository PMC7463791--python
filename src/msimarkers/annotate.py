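"""Annotation of imaging-MS m/z values by neutral-mass matching.

MALDI of tryptic peptides predominantly yields singly-protonated ions, so
an observed centroid m/z is converted to a neutral mass Mr by subtracting a
charge-carrier mass (default 1.0079 Da, the value consistent with the
published signature's printed centroid/Mr pairs; the physical proton mass
1.00728 Da can be configured instead).  Each neutral mass is then assigned
the reference peptide with the smallest absolute mass difference, and the
assignment is accepted when that difference is below the tolerance
(default 0.9 Da, the conventional bound for MALDI-imaging peptide
identification against an LC-MS/MS list).

A stricter acceptance mode additionally demands that the matched protein is
supported by more than one accepted peptide; proteins with a single
accepted peptide are then demoted.  The default keeps single-peptide
assignments, which is what the published signature table itself does.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyDataError, ParameterError
from .io_msi import ReferencePeptide

DEFAULT_CARRIER_DA = 1.0079
DEFAULT_TOLERANCE_DA = 0.9


@dataclass(frozen=True)
class MatchParams:
    """Mass-matching settings."""

    tolerance_da: float = DEFAULT_TOLERANCE_DA
    charge_carrier_da: float = DEFAULT_CARRIER_DA
    min_peptides_per_protein: int = 1

    def __post_init__(self) -> None:
        if not self.tolerance_da > 0:
            raise ParameterError("tolerance_da must be positive")
        if self.min_peptides_per_protein < 1:
            raise ParameterError("min_peptides_per_protein must be >= 1")


@dataclass
class Annotation:
    """One annotated m/z value (accepted or not)."""

    centroid_mz: float
    ims_mr: float
    lc_mr: float
    delta_da: float
    accession: str
    protein_name: str
    hgnc: str
    auc: float | None = None
    accepted: bool = False
    reason: str = ""
    shared: bool = False  # reference peptide also matched by another m/z value


def neutral_mass(centroid_mz: float, charge_carrier_da: float = DEFAULT_CARRIER_DA) -> float:
    """Neutral Mr of a singly-charged centroid: centroid minus the carrier mass."""
    if centroid_mz <= charge_carrier_da:
        raise ParameterError(
            f"centroid {centroid_mz} must exceed the charge-carrier mass {charge_carrier_da}"
        )
    return centroid_mz - charge_carrier_da


def match_reference(
    centroid_mzs,
    refs: list[ReferencePeptide],
    params: MatchParams | None = None,
    aucs=None,
) -> list[Annotation]:
    """Assign every centroid m/z its nearest reference peptide by neutral mass.

    For each input the reference with minimal |Mr(IMS) - Mr(LC)| is chosen;
    ties are broken by higher search-engine score, then lower reference
    mass, so the result does not depend on reference-list order.  Every
    input yields an :class:`Annotation`; ``accepted`` is True only when the
    mass difference is below the tolerance.
    """
    params = params or MatchParams()
    if not refs:
        raise EmptyDataError("reference list is empty")
    centroid_mzs = np.atleast_1d(np.asarray(centroid_mzs, dtype=np.float64))
    if aucs is None:
        aucs = [None] * len(centroid_mzs)

    ref_masses = np.asarray([r.neutral_mass for r in refs])
    ref_scores = np.asarray(
        [r.score if r.score is not None else -np.inf for r in refs]
    )
    annotations = []
    match_counts: Counter = Counter()
    for mz, auc in zip(centroid_mzs, aucs):
        mr = neutral_mass(float(mz), params.charge_carrier_da)
        deltas = np.abs(ref_masses - mr)
        # lexicographic: smallest delta, then highest score, then lowest mass
        order = np.lexsort((ref_masses, -ref_scores, np.round(deltas, 12)))
        best = refs[int(order[0])]
        delta = float(abs(best.neutral_mass - mr))
        accepted = delta < params.tolerance_da
        annotations.append(
            Annotation(
                centroid_mz=float(mz),
                ims_mr=mr,
                lc_mr=best.neutral_mass,
                delta_da=delta,
                accession=best.accession,
                protein_name=best.protein_name,
                hgnc=best.hgnc,
                auc=auc,
                accepted=accepted,
                reason="" if accepted else f"delta {delta:.4f} Da exceeds tolerance",
            )
        )
        if accepted:
            match_counts[best.neutral_mass] += 1
    for ann in annotations:
        ann.shared = ann.accepted and match_counts[ann.lc_mr] > 1
    if params.min_peptides_per_protein > 1:
        annotations = enforce_protein_rule(annotations, params.min_peptides_per_protein)
    return annotations


def enforce_protein_rule(annotations: list[Annotation], min_peptides: int = 2) -> list[Annotation]:
    """Demote accepted annotations whose protein lacks enough peptides.

    With ``min_peptides=2`` the conventional multi-peptide identification
    rule is enforced: accepted annotations whose accession is supported by
    fewer than two accepted peptides become ``accepted=False`` with reason
    ``"single-peptide protein"``.  With ``min_peptides=1`` the input is
    returned unchanged.
    """
    if min_peptides <= 1:
        return annotations
    support = Counter(a.accession for a in annotations if a.accepted)
    for a in annotations:
        if a.accepted and support[a.accession] < min_peptides:
            a.accepted = False
            a.reason = "single-peptide protein"
    return annotations


def annotation_table(annotations: list[Annotation]) -> pd.DataFrame:
    """Report table sorted by protein then mass difference (CSV-stable)."""
    df = pd.DataFrame(
        {
            "centroid_mz": [a.centroid_mz for a in annotations],
            "ims_mr": [a.ims_mr for a in annotations],
            "auc": [a.auc for a in annotations],
            "lc_mr": [a.lc_mr for a in annotations],
            "delta_da": [a.delta_da for a in annotations],
            "accession": [a.accession for a in annotations],
            "protein": [a.protein_name for a in annotations],
            "hgnc": [a.hgnc for a in annotations],
            "accepted": [a.accepted for a in annotations],
            "shared": [a.shared for a in annotations],
            "reason": [a.reason for a in annotations],
        }
    )
    return df.sort_values(["protein", "delta_da"], kind="mergesort").reset_index(drop=True)


def write_annotations(annotations: list[Annotation], path) -> None:
    annotation_table(annotations).to_csv(path, index=False)
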