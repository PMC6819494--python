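"""Molecular regrouping of follicular-pattern tumors.

Histology splits thyroid FNA samples into goiter, FTA, FTC, HCC, PTC, FVPTC
and MTC, but the follicular-pattern categories are molecularly heterogeneous.
The alternative grouping implemented here:

* FVPTC samples with overexpressed miR-146b behave like classic papillary
  carcinoma (PTC-like); the rest behave like follicular neoplasms (FN-like).
* Follicular neoplasms (FTA, FTC, FN-like FVPTC) with elevated HMGA2 or
  miR-221 or miR-375 form the "follicular neoplasm with markers of
  malignancy" class (FNMM); those with goiter-like levels of all three form
  FNNMM and are grouped with goiter as benign.

The final molecular classes are Benign (goiter + FNNMM), PTC, MTC, HCC and
FNMM; everything except Benign maps to a malignant binary label.

"Elevated" cutoffs are not spelled out in the source text; the defaults reuse
the published decision-tree thresholds for the same markers and every cutoff
is overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import markers as mk
from .metrics import round_half_away

MOLECULAR_CLASSES = ("Benign", "PTC", "MTC", "HCC", "FNMM")

#: molecular class -> binary malignancy label
BINARY_LABEL = {"Benign": "benign", "PTC": "malignant", "MTC": "malignant",
                "HCC": "malignant", "FNMM": "malignant"}


@dataclass(frozen=True)
class ReclassThresholds:
    """log2-scale cutoffs for "elevated" marker expression."""

    mir146b_over: float = math.log2(0.1721)   # typing-tree miR-146b split
    hmga2_over: float = math.log2(0.0918)     # malignancy-tree root
    mir221_over: float = math.log2(0.0105)    # malignancy-tree miR-221 split
    mir375_over: float = -12.1213             # malignancy-tree miR-375 split

    def __post_init__(self):
        for f in ("mir146b_over", "hmga2_over", "mir221_over", "mir375_over"):
            if not math.isfinite(getattr(self, f)):
                raise ValueError(f"{f} must be finite")


def _level(panel, marker: str):
    v = panel.get(mk.level_column(marker))
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def split_fvptc(panel, th: ReclassThresholds = ReclassThresholds()) -> str:
    """"PTC_like" if the FVPTC sample overexpresses miR-146b, else "FN_like".

    Boundary convention: a level exactly at the cutoff counts as elevated.
    """
    v = _level(panel, "miR-146b")
    if v is None:
        raise ValueError(
            f"sample {panel.get('sample_id')}: miR-146b missing, FVPTC unclassifiable"
        )
    return "PTC_like" if v >= th.mir146b_over else "FN_like"


def split_fn(panel, th: ReclassThresholds = ReclassThresholds()) -> str:
    """"FNMM" if HMGA2 or miR-221 or miR-375 is elevated, else "FNNMM"."""
    trio = {"HMGA2": th.hmga2_over, "miR-221": th.mir221_over,
            "miR-375": th.mir375_over}
    missing = [m for m in trio if _level(panel, m) is None]
    if missing:
        raise ValueError(
            f"sample {panel.get('sample_id')}: markers {missing} missing, "
            "FN split unclassifiable"
        )
    elevated = any(_level(panel, m) >= cut for m, cut in trio.items())
    return "FNMM" if elevated else "FNNMM"


def molecular_grouping(panels: pd.DataFrame,
                       th: ReclassThresholds = ReclassThresholds(),
                       errors: str = "raise"):
    """Molecular class per sample, indexed by sample_id.

    With ``errors="report"`` samples whose markers are missing are returned
    separately as a list of (sample_id, reason) instead of raising; unknown
    histotypes always raise.
    """
    out = {}
    problems: list[tuple[str, str]] = []
    for _, row in panels.iterrows():
        h = row["histotype"]
        sid = row["sample_id"]
        if h not in mk.HISTOTYPES:
            raise ValueError(f"sample {sid}: unknown histotype {h!r}")
        try:
            if h == "goiter":
                out[sid] = "Benign"
            elif h in ("PTC", "MTC", "HCC"):
                out[sid] = h
            elif h in ("FTA", "FTC"):
                out[sid] = "FNMM" if split_fn(row, th) == "FNMM" else "Benign"
            elif h == "FVPTC":
                if split_fvptc(row, th) == "PTC_like":
                    out[sid] = "PTC"
                else:
                    out[sid] = "FNMM" if split_fn(row, th) == "FNMM" else "Benign"
        except ValueError as e:
            if errors != "report":
                raise
            problems.append((sid, str(e)))
    series = pd.Series(out, name="molecular_class")
    if errors == "report":
        return series, problems
    return series


def binary_labels(grouping: pd.Series) -> pd.Series:
    """benign/malignant label per sample from the molecular class."""
    return grouping.map(BINARY_LABEL).rename("molecular_binary")


def histology_binary(histotypes: pd.Series) -> pd.Series:
    """benign/malignant label under the histological reference standard."""
    return pd.Series(
        np.where(histotypes.isin(mk.MALIGNANT_HISTOTYPES), "malignant", "benign"),
        index=histotypes.index, name="histology_binary",
    )


def composition_report(grouping: pd.Series, histotypes: pd.Series) -> pd.DataFrame:
    """Histotype composition of each molecular class, with whole-number
    percentages (half rounded away from zero).  Empty classes are omitted."""
    if set(grouping.index) <= set(histotypes.index):
        hist = histotypes.reindex(grouping.index).values
    else:  # positionally aligned vectors
        hist = np.asarray(histotypes)
    df = pd.DataFrame({"class": grouping.values, "histotype": hist})
    rows = []
    for cls, sub in df.groupby("class"):
        total = len(sub)
        for h, n in sub["histotype"].value_counts().items():
            rows.append({
                "class": cls, "histotype": h, "count": int(n), "class_total": total,
                "percent": int(round_half_away(100.0 * n / total)),
            })
    return pd.DataFrame(rows)
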