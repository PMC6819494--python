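"""Marker registry: the qPCR panel measured on every FNA smear.

The panel comprises 13 target miRNAs (malignancy markers) normalized to the
geometric mean of three endogenous reference miRNAs, HMGA2 mRNA normalized to
PGK1 mRNA, and the mitochondrial-to-nuclear DNA copy ratio.  miRNA and HMGA2
levels are stored on the log2 scale (log2 of the 2^-dCq relative quantity);
the mtDNA/nDNA ratio is stored linearly, since that is how its decision
threshold is quoted.
"""

from __future__ import annotations

# 13 malignancy-marker miRNAs (mature-strand suffixes dropped in column names)
TARGET_MIRNAS = (
    "miR-144",
    "miR-145",
    "miR-155",
    "miR-146b",
    "miR-183",
    "miR-199b",
    "miR-221",
    "miR-223",
    "miR-31",
    "miR-375",
    "miR-451a",
    "miR-551b",
    "miR-7",
)

# endogenous controls: miR-197-3p, miR-23a-3p, miR-29b-3p
REFERENCE_MIRNAS = ("miR-197", "miR-23a", "miR-29b")

HMGA2 = "HMGA2"
MTDNA = "mtDNA"

#: all markers a classifier may inspect
PANEL_MARKERS = TARGET_MIRNAS + (HMGA2, MTDNA)


def _token(marker: str) -> str:
    return marker.lower().replace("mir-", "mir").replace("-", "_")


def level_column(marker: str) -> str:
    """Column name holding a marker's normalized level in a panel table."""
    if marker == MTDNA:
        return "mtdna_ratio"
    return f"level_{_token(marker)}"


def cq_column(marker: str) -> str:
    """Column name holding a marker's raw Cq in a raw-cohort table."""
    if marker == MTDNA:
        return "cq_mtdna"
    return f"cq_{_token(marker)}"


#: storage scale per marker: miRNA/HMGA2 levels log2, mtDNA ratio linear
def storage_scale(marker: str) -> str:
    return "linear" if marker == MTDNA else "log2"


LEVEL_COLUMNS = tuple(level_column(m) for m in PANEL_MARKERS)

CQ_COLUMNS = tuple(
    [cq_column(m) for m in TARGET_MIRNAS]
    + [cq_column(m) for m in REFERENCE_MIRNAS]
    + ["cq_hmga2", "cq_pgk1", "cq_mtdna", "cq_ndna"]
)

MUTATION_COLUMNS = (
    "mut_braf_v600e",
    "mut_hras_q61r",
    "mut_nras_q61k",
    "mut_nras_q61r",
    "mut_nras_q61l",
    "fus_ret_ptc1",
    "fus_pax8_pparg",
)

RAS_COLUMNS = ("mut_hras_q61r", "mut_nras_q61k", "mut_nras_q61r", "mut_nras_q61l")

HISTOTYPES = ("goiter", "FTA", "FTC", "HCC", "PTC", "FVPTC", "MTC")

#: histotypes in which each driver event is biologically permitted
BRAF_PERMITTED = ("PTC", "FVPTC")
RET_PTC1_PERMITTED = ("PTC", "FVPTC")
PAX8_PPARG_PERMITTED = ("FTC",)

#: malignant vs benign under the histological reference standard
MALIGNANT_HISTOTYPES = ("FTC", "HCC", "PTC", "FVPTC", "MTC")

BETHESDA = {
    "goiter": "II",
    "FTA": "IV",
    "FTC": "IV",
    "HCC": "IV",
    "PTC": "VI",
    "FVPTC": "VI",
    "MTC": "VI",
    "anaplastic": "VI",
}

ID_COLUMNS = ("sample_id", "patient_id", "histotype", "bethesda", "rna_ng_ul")
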