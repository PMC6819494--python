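"""Synthetic FNA cohort generator.

No per-sample clinical table is publicly deposited for this marker panel, so
downstream stages are exercised on synthetic cohorts.  Each histotype is
described by a :class:`GroupProfile`: marker levels are drawn from normal
distributions on the log2 scale (i.e. lognormal linear quantities — an
assumption of convenience, see docs/methods.md), driver mutations from
Bernoulli draws with mutual exclusivity enforced, and the FVPTC group is an
explicit two-component mixture (papillary-like vs follicular-like) because
that heterogeneity is what the molecular regrouping is about.

The default profiles are package constants chosen so that each group sits on
the correct side of the published decision-tree thresholds (e.g. goiter HMGA2
well below the 0.0918 malignancy cutoff, PTC well above); they are synthetic,
not estimates from any patient table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import markers as mk

# log2 of the published decision thresholds, for reference when reading the
# profile constants below:
#   HMGA2 0.0918 -> -3.445;  miR-221 0.0105 -> -6.573;  miR-146b 1.5362 -> 0.620
#   miR-146b 0.1721 -> -2.539;  miR-375 (typing) 5.2514 -> 2.393
#   miR-375 (malignancy, already log2) -> -12.1213;  mtDNA 5716.3013 -> 12.481


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one histotype."""

    histotype: str
    n_samples: int
    n_patients: int
    marker_log2_mean: dict[str, float]
    marker_log2_sd: dict[str, float]
    mutation_freq: dict[str, float] = field(default_factory=dict)
    #: FVPTC only: probability a sample belongs to the papillary-like
    #: subgroup (miR-146b overexpressed); the profile means describe the
    #: follicular-like component and ``ptc_like_shift`` is added on top.
    fvptc_ptc_like_frac: float | None = None
    ptc_like_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_samples < self.n_patients or self.n_patients < 1:
            raise ValueError(
                f"{self.histotype}: need n_samples >= n_patients >= 1, "
                f"got {self.n_samples}/{self.n_patients}"
            )
        unknown = set(self.marker_log2_mean) - set(mk.PANEL_MARKERS)
        if unknown:
            raise ValueError(f"unknown marker name(s) in profile: {sorted(unknown)}")
        for m, sd in self.marker_log2_sd.items():
            if sd < 0:
                raise ValueError(f"{self.histotype}: negative SD for {m}")
        for mut, p in self.mutation_freq.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.histotype}: mutation_freq[{mut}]={p} not in [0,1]")
        if self.fvptc_ptc_like_frac is not None and not 0.0 <= self.fvptc_ptc_like_frac <= 1.0:
            raise ValueError("fvptc_ptc_like_frac must be in [0,1]")
        for m in ("HMGA2", "miR-375", "miR-221", "miR-146b", "mtDNA"):
            if m not in self.marker_log2_mean:
                raise ValueError(f"{self.histotype}: classifier marker {m} missing from profile")


@dataclass(frozen=True)
class CohortConfig:
    """Full cohort recipe; a fixed seed makes the output byte-identical."""

    profiles: tuple[GroupProfile, ...]
    seed: int = 0
    emit_raw_cq: bool = False
    reference_cq_mean: float = 24.0
    reference_cq_sd: float = 0.5
    pgk1_cq_mean: float = 27.0
    ndna_cq_mean: float = 30.0
    cq_noise_sd: float = 0.0
    rna_conc_range: tuple[float, float] = (1.2, 92.6)
    lowrna_frac: float = 0.0
    #: number of BRAF-discordant specimens to inject per non-papillary
    #: histotype, keyed by histotype (emulates pathology-report errors)
    braf_discordant: dict[str, int] = field(default_factory=dict)
    n_anaplastic: int = 0

    def __post_init__(self):
        lo, hi = self.rna_conc_range
        if not (0.0 <= lo <= hi <= 200.0):
            raise ValueError("rna_conc_range must be within [0, 200]")
        if not 0.0 <= self.lowrna_frac <= 1.0:
            raise ValueError("lowrna_frac must be in [0,1]")


# ---------------------------------------------------------------------------
# default profiles: log2 means/SDs per histotype

_BASE_MEAN = {
    "miR-144": -5.0, "miR-145": -3.5, "miR-155": -6.0, "miR-183": -6.5,
    "miR-199b": -7.0, "miR-223": -4.5, "miR-31": -6.0, "miR-451a": -3.0,
    "miR-551b": -9.0, "miR-7": -7.5,
}
_BASE_SD = {m: 1.5 for m in mk.PANEL_MARKERS}


def _profile(histotype, n_samples, n_patients, overrides, mutation_freq=None,
             marker_sd_override=None, **kw):
    mean = dict(_BASE_MEAN)
    mean.update(overrides)
    sd = dict(_BASE_SD)
    if marker_sd_override:
        sd.update(marker_sd_override)
    return GroupProfile(
        histotype=histotype,
        n_samples=n_samples,
        n_patients=n_patients,
        marker_log2_mean=mean,
        marker_log2_sd=sd,
        mutation_freq=mutation_freq or {},
        **kw,
    )


def default_profiles() -> tuple[GroupProfile, ...]:
    """Analysis-cohort profiles (sizes of the 494-sample study group).

    Group separations mirror the published marker biology: HMGA2 high in
    papillary-lineage and most follicular carcinomas; miR-146b high in
    classic PTC and the papillary-like FVPTC subgroup; miR-375 very high in
    MTC; mtDNA/nDNA ratio high in Hurthle-cell carcinoma; goiter and FTA
    low on everything.
    """
    return (
        _profile(
            "goiter", 105, 50,
            {"HMGA2": -8.0, "miR-375": -16.0, "miR-221": -9.0, "miR-146b": -6.0,
             "mtDNA": 8.0},
        ),
        _profile(
            "FTA", 101, 48,
            {"HMGA2": -7.5, "miR-375": -15.5, "miR-221": -9.0, "miR-146b": -5.5,
             "mtDNA": 8.0},
            mutation_freq={"mut_hras_q61r": 0.01, "mut_nras_q61k": 0.01},
        ),
        _profile(
            "FTC", 43, 28,
            {"HMGA2": -2.8, "miR-375": -14.0, "miR-221": -7.3, "miR-146b": -5.0,
             "mtDNA": 9.0},
            marker_sd_override={"HMGA2": 2.0},
            mutation_freq={"mut_hras_q61r": 0.16, "mut_nras_q61k": 0.10,
                           "mut_nras_q61r": 0.08, "mut_nras_q61l": 0.06,
                           "fus_pax8_pparg": 0.05},
        ),
        _profile(
            "HCC", 25, 11,
            {"HMGA2": -8.0, "miR-375": -14.0, "miR-221": -4.5, "miR-146b": -6.0,
             "mtDNA": 14.5},
            marker_sd_override={"mtDNA": 1.0, "miR-221": 1.2},
            mutation_freq={"mut_hras_q61r": 0.08, "mut_nras_q61k": 0.08},
        ),
        _profile(
            "PTC", 121, 56,
            {"HMGA2": -0.4, "miR-375": -9.0, "miR-221": -5.8, "miR-146b": 2.0,
             "mtDNA": 8.5},
            marker_sd_override={"HMGA2": 2.0, "miR-221": 1.8},
            mutation_freq={"mut_braf_v600e": 0.35, "fus_ret_ptc1": 0.10,
                           "mut_nras_q61r": 0.03, "mut_nras_q61k": 0.02},
        ),
        _profile(
            "FVPTC", 80, 32,
            {"HMGA2": -2.0, "miR-375": -12.0, "miR-221": -6.2, "miR-146b": -6.0,
             "mtDNA": 8.5},
            marker_sd_override={"HMGA2": 2.0, "miR-221": 1.6, "miR-146b": 1.3},
            mutation_freq={"mut_braf_v600e": 0.15, "fus_ret_ptc1": 0.05,
                           "mut_hras_q61r": 0.20, "mut_nras_q61k": 0.12,
                           "mut_nras_q61r": 0.10, "mut_nras_q61l": 0.06},
            fvptc_ptc_like_frac=0.54,
            ptc_like_shift={"miR-146b": 8.0, "HMGA2": 1.0},
        ),
        _profile(
            "MTC", 19, 12,
            {"HMGA2": -7.5, "miR-375": 5.0, "miR-221": -6.8, "miR-146b": -7.0,
             "mtDNA": 9.0},
            marker_sd_override={"miR-375": 1.2},
            mutation_freq={"mut_hras_q61r": 0.11, "mut_nras_q61k": 0.10},
        ),
    )


def scaled_profiles(factor: int) -> tuple[GroupProfile, ...]:
    """Default profiles with every group's sample and patient counts
    multiplied by ``factor`` (study prevalences preserved); for experiments
    needing large per-group n."""
    return tuple(
        replace(p, n_samples=p.n_samples * factor, n_patients=p.n_patients * factor)
        for p in default_profiles()
    )


def default_config(seed: int = 0, emit_raw_cq: bool = False,
                   pre_exclusion: bool = False) -> CohortConfig:
    """Default cohort recipe.

    With ``pre_exclusion=True`` the generator emits the full accession-stage
    cohort: 107 goiter / 103 FTA / 44 FTC / 25 HCC / 121 PTC / 80 FVPTC /
    19 MTC plus 2 anaplastic specimens, where the histotype surpluses are
    BRAF-discordant specimens (2 goiter, 2 FTA, 1 FTC) destined for QC
    exclusion, leaving 494 samples for analysis.
    """
    profiles = default_profiles()
    if not pre_exclusion:
        return CohortConfig(profiles=profiles, seed=seed, emit_raw_cq=emit_raw_cq)
    bumped = []
    extra = {"goiter": 2, "FTA": 2, "FTC": 1}
    for p in profiles:
        add = extra.get(p.histotype, 0)
        bumped.append(replace(p, n_samples=p.n_samples + add))
    return CohortConfig(
        profiles=tuple(bumped), seed=seed, emit_raw_cq=emit_raw_cq,
        braf_discordant=extra, n_anaplastic=2,
    )


# ---------------------------------------------------------------------------

def levels_to_cq(level_log2: float, reference_cq: float) -> float:
    """Invert the 2^-dCq normalization: the target Cq that would produce
    ``level_log2`` against a reference Cq (arithmetic mean of controls).

    Values outside the instrument's detection window (0, 45) are the
    caller's signal to encode a non-detect.
    """
    if not 0.0 < reference_cq < 45.0:
        raise ValueError(f"reference_cq {reference_cq} outside (0, 45)")
    return reference_cq - level_log2


def _draw_mutations(rng: np.random.Generator, freq: dict[str, float], n: int,
                    histotype: str) -> dict[str, np.ndarray]:
    flags = {c: np.zeros(n, dtype=int) for c in mk.MUTATION_COLUMNS}
    for col, p in freq.items():
        if col not in flags:
            raise ValueError(f"unknown mutation column {col!r}")
        flags[col] = (rng.random(n) < p).astype(int)
    # tumor-type specificity of the drivers
    if histotype not in mk.BRAF_PERMITTED:
        flags["mut_braf_v600e"][:] = 0
        flags["fus_ret_ptc1"][:] = 0
    if histotype not in mk.PAX8_PPARG_PERMITTED:
        flags["fus_pax8_pparg"][:] = 0
    # mutual exclusivity of driver events, fixed priority BRAF > RET-PTC1 > RAS
    priority = ("mut_braf_v600e", "fus_ret_ptc1") + mk.RAS_COLUMNS
    taken = np.zeros(n, dtype=bool)
    for col in priority:
        keep = (flags[col] == 1) & ~taken
        flags[col] = keep.astype(int)
        taken |= keep
    return flags


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one synthetic cohort table.

    Returns a normalized marker-panel table (``level_*`` columns, log2;
    ``mtdna_ratio`` linear) or, with ``emit_raw_cq``, a raw-Cq table from
    which :func:`thyromir.normalize.normalize_table` recovers the same
    levels exactly when ``cq_noise_sd`` is zero.
    """
    blocks: list[pd.DataFrame] = []
    patient_counter = 0
    sample_counter = 0

    for prof_idx, prof in enumerate(config.profiles):
        # one independent stream per profile, and raw-Cq draws consumed after
        # the level draws: the same seed yields the same marker levels in
        # panel and raw modes
        rng = np.random.default_rng([config.seed, prof_idx])
        n = prof.n_samples
        rows: dict[str, object] = {}
        rows["sample_id"] = [f"S{sample_counter + i:04d}" for i in range(n)]
        sample_counter += n
        # round-robin assignment of samples to patients
        rows["patient_id"] = [
            f"P{patient_counter + (i % prof.n_patients):03d}" for i in range(n)
        ]
        patient_counter += prof.n_patients
        rows["histotype"] = [prof.histotype] * n
        rows["bethesda"] = [mk.BETHESDA[prof.histotype]] * n

        lo, hi = config.rna_conc_range
        conc = rng.uniform(max(lo, 5.0), hi, size=n)
        n_low = int(round(config.lowrna_frac * n))
        if n_low:
            idx = rng.choice(n, size=n_low, replace=False)
            conc[idx] = rng.uniform(lo, 5.0, size=n_low)
        rows["rna_ng_ul"] = np.round(conc, 1)

        levels = {}
        ptc_like = None
        if prof.fvptc_ptc_like_frac is not None:
            ptc_like = rng.random(n) < prof.fvptc_ptc_like_frac
        for m in mk.PANEL_MARKERS:
            mu, sd = prof.marker_log2_mean[m], prof.marker_log2_sd[m]
            v = rng.normal(mu, sd, size=n) if sd > 0 else np.full(n, mu)
            if ptc_like is not None and m in prof.ptc_like_shift:
                v = v + np.where(ptc_like, prof.ptc_like_shift[m], 0.0)
            levels[m] = v

        flags = _draw_mutations(rng, prof.mutation_freq, n, prof.histotype)

        block = pd.DataFrame(rows)
        if config.emit_raw_cq:
            ref = rng.normal(config.reference_cq_mean, config.reference_cq_sd,
                             size=(n, 3))
            for j, rm in enumerate(mk.REFERENCE_MIRNAS):
                block[mk.cq_column(rm)] = np.round(ref[:, j], 4)
            ref_mean = np.round(ref, 4).mean(axis=1)
            noise = (lambda: rng.normal(0.0, config.cq_noise_sd, size=n)) \
                if config.cq_noise_sd > 0 else (lambda: 0.0)
            for m in mk.TARGET_MIRNAS:
                block[mk.cq_column(m)] = ref_mean - levels[m] + noise()
            pgk1 = rng.normal(config.pgk1_cq_mean, config.reference_cq_sd, size=n)
            block["cq_pgk1"] = pgk1
            block["cq_hmga2"] = pgk1 - levels["HMGA2"] + noise()
            ndna = rng.normal(config.ndna_cq_mean, config.reference_cq_sd, size=n)
            block["cq_ndna"] = ndna
            block["cq_mtdna"] = ndna - levels["mtDNA"] + noise()
        else:
            for m in mk.TARGET_MIRNAS:
                block[mk.level_column(m)] = levels[m]
            block[mk.level_column(mk.HMGA2)] = levels["HMGA2"]
            # mtDNA levels are generated on log2 scale; the panel stores the
            # linear copy ratio
            block["mtdna_ratio"] = np.exp2(levels["mtDNA"])
        for col in mk.MUTATION_COLUMNS:
            block[col] = flags[col]
        blocks.append(block)

    table = pd.concat(blocks, ignore_index=True)

    # inject BRAF-discordant specimens: flip the BRAF flag on the first
    # requested samples of each non-papillary histotype
    for histotype, count in config.braf_discordant.items():
        idx = table.index[table["histotype"] == histotype][:count]
        table.loc[idx, "mut_braf_v600e"] = 1
        for col in ("fus_ret_ptc1",) + mk.RAS_COLUMNS:
            table.loc[idx, col] = 0

    if config.n_anaplastic:
        ana_rng = np.random.default_rng([config.seed, 10_000])
        table = pd.concat(
            [table, _anaplastic_block(ana_rng, config, sample_counter, patient_counter)],
            ignore_index=True,
        )
    return table


def _anaplastic_block(rng, config, sample_start, patient_start) -> pd.DataFrame:
    """Anaplastic specimens: HMGA2-high, set aside before classification."""
    n = config.n_anaplastic
    rows = {
        "sample_id": [f"S{sample_start + i:04d}" for i in range(n)],
        "patient_id": [f"P{patient_start + i:03d}" for i in range(n)],
        "histotype": ["anaplastic"] * n,
        "bethesda": ["VI"] * n,
        "rna_ng_ul": np.round(rng.uniform(5.0, config.rna_conc_range[1], size=n), 1),
    }
    block = pd.DataFrame(rows)
    lvl = {
        "HMGA2": rng.normal(-1.0, 1.0, size=n),
        "miR-375": rng.normal(-13.0, 1.5, size=n),
        "miR-221": rng.normal(-6.0, 1.5, size=n),
        "miR-146b": rng.normal(-4.0, 1.5, size=n),
        "mtDNA": rng.normal(9.0, 1.5, size=n),
    }
    if config.emit_raw_cq:
        ref = rng.normal(config.reference_cq_mean, config.reference_cq_sd, size=(n, 3))
        for j, rm in enumerate(mk.REFERENCE_MIRNAS):
            block[mk.cq_column(rm)] = np.round(ref[:, j], 4)
        ref_mean = np.round(ref, 4).mean(axis=1)
        for m in mk.TARGET_MIRNAS:
            mu = lvl.get(m)
            v = mu if mu is not None else rng.normal(_BASE_MEAN.get(m, -5.0), 1.5, size=n)
            block[mk.cq_column(m)] = ref_mean - v
        pgk1 = rng.normal(config.pgk1_cq_mean, config.reference_cq_sd, size=n)
        block["cq_pgk1"] = pgk1
        block["cq_hmga2"] = pgk1 - lvl["HMGA2"]
        ndna = rng.normal(config.ndna_cq_mean, config.reference_cq_sd, size=n)
        block["cq_ndna"] = ndna
        block["cq_mtdna"] = ndna - lvl["mtDNA"]
    else:
        for m in mk.TARGET_MIRNAS:
            mu = lvl.get(m)
            v = mu if mu is not None else rng.normal(_BASE_MEAN.get(m, -5.0), 1.5, size=n)
            block[mk.level_column(m)] = v
        block[mk.level_column(mk.HMGA2)] = lvl["HMGA2"]
        block["mtdna_ratio"] = np.exp2(lvl["mtDNA"])
    for col in mk.MUTATION_COLUMNS:
        block[col] = 0
    return block
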