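"""Published prognostic peptide signature for early-stage HGSOC.

Eighteen discriminative MALDI-imaging m/z values (singly-protonated tryptic
peptide centroids) with their ROC AUC for recurrent vs non-recurrent
disease and the LC-MS/MS reference peptides they were assigned to.  This
table serves as the worked example for the annotation stage: feeding the
centroids and reference masses through the mass-matching rules reproduces
the printed neutral masses and mass differences.
"""

from __future__ import annotations

import pandas as pd

from .io_msi import ReferencePeptide

# columns: centroid m/z (MH+), AUC (+RD vs -RD), LC-MS/MS neutral Mr (Da),
#          accession, protein name, HGNC symbol
HGSOC_SIGNATURE: list[tuple[float, float, float, str, str, str]] = [
    (2705.026, 0.7547, 2704.1538, "K1C9_HUMAN", "Keratin, type I cytoskeletal 9", "KRT9"),
    (1791.698, 0.6250, 1790.7204, "K1C9_HUMAN", "Keratin, type I cytoskeletal 9", "KRT9"),
    (644.336, 0.7470, 643.3653, "ACTB_HUMAN", "Actin, cytoplasmic 1", "ACTB"),
    (840.564, 0.7407, 839.4613, "CO1A2_HUMAN", "Collagen alpha-2(I) chain", "COL1A2"),
    (868.467, 0.7331, 867.4563, "CO1A2_HUMAN", "Collagen alpha-2(I) chain", "COL1A2"),
    (2027.831, 0.7008, 2026.0093, "CO1A2_HUMAN", "Collagen alpha-2(I) chain", "COL1A2"),
    (1562.765, 0.6930, 1561.7849, "CO1A2_HUMAN", "Collagen alpha-2(I) chain", "COL1A2"),
    (1223.417, 0.6262, 1222.6054, "CO1A2_HUMAN", "Collagen alpha-2(I) chain", "COL1A2"),
    (700.444, 0.6388, 699.4643, "RL37A_HUMAN", "60S ribosomal protein L37a", "RPL37A"),
    (1790.797, 0.6253, 1789.8846, "ACTB_HUMAN", "Actin, cytoplasmic 1", "ACTB"),
    (1743.691, 0.6055, 1742.8120, "H2B1N_HUMAN", "Histone H2B type 1-N", "HIST1H2BN"),
    (1550.764, 0.6016, 1549.8100, "ANXA1_HUMAN", "Annexin A1", "ANXA1"),
    (858.566, 0.3975, 857.4607, "CALD1_HUMAN", "Caldesmon", "CALD1"),
    (1157.708, 0.3782, 1156.6200, "APOA1_HUMAN", "Apolipoprotein A-I", "APOA1"),
    (1631.775, 0.3682, 1630.8236, "TBB5_HUMAN", "Tubulin beta chain", "TUBB"),
    (1751.792, 0.3554, 1750.0353, "H2B1K_HUMAN", "Histone H2B type 1-K", "HIST1H2BK"),
    (1055.394, 0.3460, 1054.5196, "4_HUMAN", "Histone H4", "HIST1H4A"),
    (1752.992, 0.3159, 1751.8551, "LMNA_HUMAN", "Prelamin-A/C", "LMNA"),
]


def signature_frame() -> pd.DataFrame:
    """The signature as a DataFrame (one row per discriminative m/z value)."""
    return pd.DataFrame(
        HGSOC_SIGNATURE,
        columns=["centroid_mz", "auc", "lc_mr", "accession", "protein", "hgnc"],
    )


def signature_reference_list() -> list[ReferencePeptide]:
    """The signature's LC-MS/MS peptides as a reference list for matching."""
    return [
        ReferencePeptide(
            neutral_mass=lc_mr, accession=acc, protein_name=protein, hgnc=hgnc
        )
        for (_mz, _auc, lc_mr, acc, protein, hgnc) in HGSOC_SIGNATURE
    ]
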