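"""Cq-to-level normalization and sample-level QC exclusions.

Relative quantities follow the 2^-dCq convention.  For miRNAs the reference
quantity is the geometric mean of the three endogenous control miRNAs, which
on the Cq scale is simply the arithmetic mean of their Cq values, so

    log2 level = mean(Cq_ref1, Cq_ref2, Cq_ref3) - Cq_target.

HMGA2 mRNA is normalized to PGK1 mRNA and the mtDNA/nDNA copy ratio to the
nuclear-DNA Cq by the same rule.  Levels are kept on the log2 scale except
the mtDNA/nDNA ratio, reported linearly.

QC rules: samples with total-RNA concentration strictly below 5 ng/ul are
excluded; samples carrying BRAF V600E while labelled with a non-papillary
histotype are excluded as presumed pathology-report errors.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from . import markers as mk

#: Cq values outside this range are treated as non-detects (missing)
CQ_VALID_RANGE = (0.0, 45.0)

#: default total-RNA exclusion threshold, ng/ul
LOW_RNA_THRESHOLD = 5.0


def normalize_mirna(cq_target, cq_ref1, cq_ref2, cq_ref3):
    """log2 relative miRNA level vs the geometric mean of three references.

    Any missing input yields a missing (NaN) level; missingness is never
    silently mapped to zero.  Accepts scalars or aligned numpy/pandas arrays.
    """
    ref_mean = (
        np.asarray(cq_ref1, dtype=float)
        + np.asarray(cq_ref2, dtype=float)
        + np.asarray(cq_ref3, dtype=float)
    ) / 3.0
    out = ref_mean - np.asarray(cq_target, dtype=float)
    if out.ndim == 0:
        return float(out)
    return out


def normalize_hmga2(cq_hmga2, cq_pgk1):
    """log2 relative HMGA2 mRNA level vs PGK1 (2^-dCq on log2 scale)."""
    out = np.asarray(cq_pgk1, dtype=float) - np.asarray(cq_hmga2, dtype=float)
    if out.ndim == 0:
        return float(out)
    return out


def mtdna_ratio(cq_mt, cq_n):
    """Linear mitochondrial-to-nuclear DNA copy ratio, 2^(Cq_n - Cq_mt)."""
    out = np.exp2(np.asarray(cq_n, dtype=float) - np.asarray(cq_mt, dtype=float))
    if out.ndim == 0:
        return float(out)
    return out


def _mask_nondetect(cq: pd.Series) -> pd.Series:
    lo, hi = CQ_VALID_RANGE
    return cq.where((cq > lo) & (cq < hi))


def normalize_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Convert a raw-Cq cohort table into a normalized marker-panel table.

    Keeps identifier and mutation columns; replaces ``cq_*`` columns with
    ``level_*`` (log2) columns and ``mtdna_ratio``.  Cq values outside
    (0, 45) are treated as non-detects and propagate as missing levels.
    """
    missing = [c for c in ("cq_mir197", "cq_mir23a", "cq_mir29b") if c not in raw]
    if missing:
        raise ValueError(f"raw table lacks reference miRNA columns: {missing}")

    out = raw[[c for c in raw.columns if not c.startswith("cq_")]].copy()
    r1 = _mask_nondetect(raw["cq_mir197"].astype(float))
    r2 = _mask_nondetect(raw["cq_mir23a"].astype(float))
    r3 = _mask_nondetect(raw["cq_mir29b"].astype(float))
    ref_mean = (r1 + r2 + r3) / 3.0

    for m in mk.TARGET_MIRNAS:
        col = mk.cq_column(m)
        if col in raw:
            out[mk.level_column(m)] = ref_mean - _mask_nondetect(raw[col].astype(float))
    if "cq_hmga2" in raw and "cq_pgk1" in raw:
        out[mk.level_column(mk.HMGA2)] = _mask_nondetect(
            raw["cq_pgk1"].astype(float)
        ) - _mask_nondetect(raw["cq_hmga2"].astype(float))
    if "cq_mtdna" in raw and "cq_ndna" in raw:
        out["mtdna_ratio"] = np.exp2(
            _mask_nondetect(raw["cq_ndna"].astype(float))
            - _mask_nondetect(raw["cq_mtdna"].astype(float))
        )
    return out


def qc_low_rna(records: pd.DataFrame, threshold: float = LOW_RNA_THRESHOLD):
    """Split a table into (retained, excluded) by total-RNA concentration.

    Exclusion is strict: a sample at exactly the threshold is retained.
    Row order is preserved in both outputs.
    """
    if "rna_ng_ul" not in records:
        raise ValueError("records lack the rna_ng_ul column")
    low = records["rna_ng_ul"].astype(float) < threshold
    return records.loc[~low], records.loc[low]


def braf_discordance_filter(panels: pd.DataFrame):
    """Exclude samples with BRAF V600E but a non-papillary histotype.

    BRAF V600E is specific to papillary carcinoma, so its detection in a
    sample reported as goiter/FTA/FTC/HCC flags a presumed pathology-report
    error; such samples are removed from analysis.  Samples with a missing
    BRAF flag are retained with a warning.
    """
    flag = panels["mut_braf_v600e"]
    if flag.isna().any():
        warnings.warn(
            f"{int(flag.isna().sum())} samples have no BRAF V600E result; retained",
            stacklevel=2,
        )
    non_ptc = ~panels["histotype"].isin(mk.BRAF_PERMITTED)
    discordant = (flag == 1) & non_ptc & panels["histotype"].isin(mk.HISTOTYPES)
    return panels.loc[~discordant], panels.loc[discordant]


def anaplastic_filter(table: pd.DataFrame):
    """Set aside anaplastic-carcinoma specimens (too few to classify)."""
    ana = table["histotype"] == "anaplastic"
    return table.loc[~ana], table.loc[ana]


def linear(level_log2: float) -> float:
    """Linear 2^-dCq quantity from a log2 level."""
    return math.exp2(level_log2)
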