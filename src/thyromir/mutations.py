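"""Somatic mutation and translocation logic.

The panel genotypes five point mutations (BRAF V600E; HRAS Q61R; NRAS
Q61K/Q61R/Q61L) and two rearrangements (RET-PTC1; PAX8-PPARG).  Two rules
derive from their tumor-type specificity: BRAF V600E and RET-PTC1 occur in
papillary carcinomas only and PAX8-PPARG in follicular carcinomas only, and
the driver events are (with rare exceptions) mutually exclusive.  RAS
mutations cut across types, which makes "RAS-positive => malignant" a natural
but weak rule for follicular neoplasms; quantifying exactly how weak is the
point of :func:`ras_fn_confusion`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import markers as mk
from .metrics import ConfusionMatrix


def ras_any(panels: pd.DataFrame) -> pd.Series:
    """1 if any RAS codon-61 flag is set; missing flags count as negative."""
    flags = panels[list(mk.RAS_COLUMNS)].fillna(0).astype(int)
    return (flags.sum(axis=1) > 0).astype(int)


def ras_fn_confusion(fn_panels: pd.DataFrame) -> ConfusionMatrix:
    """2x2 confusion matrix for calling follicular neoplasms malignant by
    RAS-mutation status (truth: FTC malignant, FTA benign)."""
    bad = fn_panels.loc[~fn_panels["histotype"].isin(["FTA", "FTC"])]
    if len(bad):
        raise ValueError(
            "ras_fn_confusion expects only FTA/FTC samples; offending: "
            + ", ".join(map(str, bad["sample_id"].head(5).tolist()))
        )
    truth = np.where(fn_panels["histotype"] == "FTC", "malignant", "benign")
    pred = np.where(ras_any(fn_panels) == 1, "malignant", "benign")
    return ConfusionMatrix.from_labels(truth, pred, classes=("malignant", "benign"))


def mutation_specificity_report(panels: pd.DataFrame):
    """Contingency table of mutation counts by histotype plus a list of
    specificity-rule violations.

    Violations flagged (reported, never dropped): BRAF V600E or RET-PTC1
    outside the papillary family, PAX8-PPARG outside FTC, and co-occurring
    driver events in one sample.
    """
    counts = pd.DataFrame(
        0,
        index=pd.Index(sorted(panels["histotype"].unique()), name="histotype"),
        columns=list(mk.MUTATION_COLUMNS),
        dtype=int,
    )
    for col in mk.MUTATION_COLUMNS:
        if col in panels:
            got = panels.groupby("histotype")[col].apply(
                lambda s: int((s.fillna(0) == 1).sum())
            )
            counts.loc[got.index, col] = got

    violations = []
    flags = panels[list(mk.MUTATION_COLUMNS)].fillna(0).astype(int)
    drivers = ["mut_braf_v600e", "fus_ret_ptc1"] + list(mk.RAS_COLUMNS)
    for i, row in panels.iterrows():
        f = flags.loc[i]
        h = row["histotype"]
        sid = row.get("sample_id", i)
        if f["mut_braf_v600e"] and h not in mk.BRAF_PERMITTED:
            violations.append((sid, f"BRAF V600E in {h}"))
        if f["fus_ret_ptc1"] and h not in mk.RET_PTC1_PERMITTED:
            violations.append((sid, f"RET-PTC1 in {h}"))
        if f["fus_pax8_pparg"] and h not in mk.PAX8_PPARG_PERMITTED:
            violations.append((sid, f"PAX8-PPARG in {h}"))
        n_drivers = int(f["mut_braf_v600e"]) + int(f["fus_ret_ptc1"]) + int(
            f[list(mk.RAS_COLUMNS)].sum() > 0
        )
        if n_drivers > 1:
            violations.append((sid, "co-occurring driver events"))

    missing = panels[list(mk.MUTATION_COLUMNS)].isna().sum()
    return counts, violations, missing
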