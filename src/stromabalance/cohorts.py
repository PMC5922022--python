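"""Inventory of the seven public prostate-cancer cohorts the method targets.

Published sample counts per cohort (accession, platform class, cancer and
normal sample numbers, unique gene count, and whether histopathology tissue
percentages are available for every sample).  The two histopathology cohorts
(Bertilsson, Chen) seed the stroma gene-sets; the five cohorts containing
both cancer and normal samples form the five-study meta-cohort, and all
seven form the seven-study meta-cohort.  Only the metadata is bundled — the
expression data themselves live at the listed public accessions.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["cohort_inventory", "study_group_counts"]

_ROWS = [
    # name, accession, platform, n_cancer, n_normal, n_genes, histopathology
    ("Bertilsson", "E-MTAB-1041", "microarray", 116, 40, 14149, True),
    ("Chen", "GSE8218", "microarray", 65, 71, 12497, True),
    ("Taylor", "GSE21034", "microarray", 131, 29, 18294, False),
    ("TCGA", "TCGA", "rna-seq", 497, 52, 20504, False),
    ("Prensner", "phs000443.v1.p1", "rna-seq", 78, 38, 23712, False),
    ("Sboner", "GSE16560", "microarray", 281, 0, 6102, False),
    ("Erho", "GSE46691", "exon-array", 545, 0, 17163, False),
]

FIVE_STUDY = ("Bertilsson", "Chen", "Taylor", "TCGA", "Prensner")
SEVEN_STUDY = FIVE_STUDY + ("Sboner", "Erho")


def cohort_inventory() -> pd.DataFrame:
    """The seven-cohort metadata table, one row per cohort."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "cohort",
            "accession",
            "platform",
            "n_cancer",
            "n_normal",
            "n_genes",
            "histopathology",
        ],
    )


def study_group_counts(group: str = "five") -> dict[str, int]:
    """Total cancer/normal/sample counts for the five- or seven-study group."""
    names = {"five": FIVE_STUDY, "seven": SEVEN_STUDY}.get(group)
    if names is None:
        raise ValueError("group must be 'five' or 'seven'")
    inv = cohort_inventory().set_index("cohort").loc[list(names)]
    n_cancer = int(inv["n_cancer"].sum())
    n_normal = int(inv["n_normal"].sum())
    return {"n_cancer": n_cancer, "n_normal": n_normal, "n_samples": n_cancer + n_normal}
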