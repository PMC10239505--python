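"""Synthetic post-mortem brain cohort generator with known planted effects.

The generator reproduces the statistical structure the downstream analysis
assumes: four subject groups (controls and Parkinson's disease with normal
cognition, mild cognitive impairment, or dementia), two brain regions with
unequal coverage (no demented-subject putamen samples), two cortex plates
with multiplicative per-analyte batch factors, log-normal analyte
abundances with group-specific residual scale, limit-of-detection censoring
driven by simulated blank signals, sociodemographic covariates close to the
study cohort's distributions, and an acute-levodopa state that shifts a
DOPA analyte and optionally interacts with planted effects.

Effects are planted on the log scale in units of the control residual SD,
so that after log-like Box-Cox transformation and standardization to
controls the regression coefficients recover them directly. Every draw
derives from a single seed via spawned SeedSequence streams (one per
analyte), so cohorts are bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GROUPS, SCORES, AnalyteTable, SampleMeta

PD_GROUPS = ("PD-CN", "PD-MCI", "PD-D")

# Cohort-characteristic targets (mean/SD by group CTRL, PD-CN, PD-MCI, PD-D)
_AGE = {"CTRL": (82, 10), "PD-CN": (85, 6), "PD-MCI": (82, 6), "PD-D": (80, 5)}
_BMI = {"CTRL": (25, 5), "PD-CN": (22, 4), "PD-MCI": (25, 8), "PD-D": (27, 9)}
_EDU = (14.5, 3.0)
_SEX_M = {"CTRL": 0.61, "PD-CN": 0.57, "PD-MCI": 0.74, "PD-D": 0.75}
_STORAGE = {"CTRL": (10, 4), "PD-CN": (8, 4), "PD-MCI": (6, 4), "PD-D": (8, 4)}
_COMORB = {
    "hyperlipidemia": {"CTRL": 0.36, "PD-CN": 0.50, "PD-MCI": 0.47, "PD-D": 0.34},
    "diabetes": {"CTRL": 0.33, "PD-CN": 0.07, "PD-MCI": 0.16, "PD-D": 0.25},
    "renal_insufficiency": {"CTRL": 0.14, "PD-CN": 0.21, "PD-MCI": 0.11, "PD-D": 0.16},
    "hypothyroidism": {"CTRL": 0.25, "PD-CN": 0.21, "PD-MCI": 0.26, "PD-D": 0.16},
}
_SCORE_PARAMS = {
    "pd_duration": {"PD-CN": (11, 7), "PD-MCI": (12, 6), "PD-D": (18, 9)},
    "updrs_m": {"CTRL": (7, 5), "PD-CN": (32, 15), "PD-MCI": (31, 15), "PD-D": (50, 16)},
    "usslb": {"CTRL": (0.0, 0.05), "PD-CN": (3.0, 0.5), "PD-MCI": (3.7, 0.5),
              "PD-D": (3.4, 0.6)},
    "mmse": {"CTRL": (28, 1), "PD-CN": (28, 1), "PD-MCI": (25, 3), "PD-D": (20, 6)},
    "plaque_density": {"CTRL": (2.7, 3.9), "PD-CN": (4.6, 4.7), "PD-MCI": (5.1, 6.0),
                       "PD-D": (1.8, 3.3)},
    "tangle_density": {"CTRL": (2.9, 1.6), "PD-CN": (5.3, 2.6), "PD-MCI": (5.2, 1.6),
                       "PD-D": (4.8, 2.1)},
}
_SCORE_MISSING = {"updrs_m": 0.4, "mmse": 0.2}


@dataclass
class SimConfig:
    """All knobs of the cohort generator.

    Planted effects are dictionaries keyed by ``(analyte_id, key)`` with
    values in control-SD units on the log scale: ``group_effects`` by
    subject group, ``levodopa_effects`` by ``PD-ND``/``PD-D`` (applied to
    acutely medicated subjects only), ``score_effects`` by progression
    score (slope per PD-subject SD of the score). ``covariate_effects`` is
    keyed by covariate name and applies to every subject sample.
    """

    n_cortex: dict = field(default_factory=lambda: {
        "CTRL": 36, "PD-CN": 14, "PD-MCI": 19, "PD-D": 32})
    n_putamen: dict = field(default_factory=lambda: {
        "CTRL": 35, "PD-CN": 14, "PD-MCI": 19, "PD-D": 0})
    n_analytes_lc: int = 30
    n_analytes_fia: int = 70
    named_analytes: tuple = ()          # extra LC measured analytes, by name
    n_plates_cortex: int = 2
    n_qc_per_plate: int = 3
    plate_factor_sigma: float = 0.15    # log-SD of per-analyte plate factors
    qc_cv: float = 0.05                 # log-SD of QC repeats
    analyte_sigma_range: tuple = (0.2, 0.6)   # control residual log-SD range
    group_sigma_scale: dict = field(default_factory=lambda: {
        "CTRL": 1.0, "PD-CN": 1.0, "PD-MCI": 1.0, "PD-D": 1.0})
    group_effects: dict = field(default_factory=dict)
    levodopa_effects: dict = field(default_factory=dict)
    score_effects: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)
    frac_levodopa_positive: float = 0.5
    dopa_separation: float = 4.0        # L+ shift of DOPA, in DOPA log-SD units
    lod_censor_quantile: float = 0.02   # target fraction of cells below LOD
    bmi_missing: float = 0.04
    education_missing: float = 0.04
    block_size: int = 0                 # >1 enables block-correlated residuals
    block_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for d in (self.n_cortex, self.n_putamen):
            if any(v < 0 for v in d.values()):
                raise ValueError("group counts must be >= 0")
            if set(d) != set(GROUPS):
                raise ValueError(f"group counts must cover {GROUPS}")
        if not 0 <= self.frac_levodopa_positive <= 1:
            raise ValueError("frac_levodopa_positive must be in [0, 1]")
        if self.plate_factor_sigma < 0:
            raise ValueError("plate_factor_sigma must be >= 0")
        if sum(self.n_cortex.values()) + sum(self.n_putamen.values()) == 0:
            raise ValueError("no samples in any group")
        for g in GROUPS:
            if self.n_putamen[g] > self.n_cortex[g]:
                raise ValueError("putamen subjects must be a subset of cortex subjects")
        if self.n_putamen["PD-D"] > 0:
            raise ValueError("the study design has no PD-D putamen samples")


@dataclass
class SimTruth:
    """Everything the generator actually used, for parameter-recovery tests."""

    config: SimConfig
    analyte_log_mean: pd.Series
    analyte_log_sd: pd.Series           # control residual SD on the log scale
    plate_factors: pd.DataFrame         # analyte x plate multiplicative factors
    lplus: dict                         # subject_id -> bool (PD subjects only)
    lod: pd.Series                      # analyte -> simulated LOD
    censored: pd.DataFrame              # samples x analytes, True below LOD
    expected_qc_conc: pd.Series         # analyte -> nominal QC concentration, µM
    group_effects: dict
    levodopa_effects: dict
    score_effects: dict
    covariate_effects: dict


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def _make_subjects(cfg: SimConfig, rng) -> pd.DataFrame:
    rows = []
    for g in GROUPS:
        for i in range(cfg.n_cortex[g]):
            sid = f"{g.replace('-', '')}{i + 1:03d}"
            m_age, s_age = _AGE[g]
            m_bmi, s_bmi = _BMI[g]
            m_sto, s_sto = _STORAGE[g]
            row = {
                "subject_id": sid,
                "group": g,
                "age": round(float(_truncnorm(rng, m_age, s_age, 55, 102)), 1),
                "sex": "M" if rng.random() < _SEX_M[g] else "F",
                "education": round(float(_truncnorm(rng, *_EDU, 6, 22)), 1),
                "bmi": round(float(_truncnorm(rng, m_bmi, s_bmi, 15, 48)), 1),
                "pmci": round(float(rng.lognormal(np.log(3.2), 0.3)), 2),
                "storage": round(float(_truncnorm(rng, m_sto, s_sto, 0.5, 25)), 1),
            }
            for c, probs in _COMORB.items():
                row[c] = int(rng.random() < probs[g])
            for sc, params in _SCORE_PARAMS.items():
                if g in params:
                    m, s = params[g]
                    lo = 0.5 if sc == "pd_duration" else 0.0
                    hi = 30 if sc == "mmse" else np.inf
                    val = float(_truncnorm(rng, m, s, lo, hi))
                    if rng.random() < _SCORE_MISSING.get(sc, 0.0):
                        val = np.nan
                    row[sc] = round(val, 1)
                else:
                    row[sc] = np.nan
            rows.append(row)
    df = pd.DataFrame(rows).set_index("subject_id", drop=False)
    # a few missing sociodemographics, to exercise imputation
    for col, frac in (("bmi", cfg.bmi_missing), ("education", cfg.education_missing)):
        n_miss = int(round(frac * len(df)))
        if n_miss:
            idx = rng.choice(len(df), size=n_miss, replace=False)
            df.iloc[idx, df.columns.get_loc(col)] = np.nan
    return df


def _assign_plates(groups: pd.Series, plates: list[str], rng) -> pd.Series:
    """Stratified randomization of samples to plates within each group."""
    out = pd.Series(index=groups.index, dtype=object)
    for g in groups.unique():
        idx = groups.index[groups == g]
        perm = rng.permutation(len(idx))
        for k, i in enumerate(perm):
            out[idx[i]] = plates[k % len(plates)]
    return out


def simulate_cohort(cfg: SimConfig):
    """Generate one cohort.

    Returns ``(table, meta, blanks, truth)`` where ``table`` is the raw
    area-ratio :class:`AnalyteTable` (subject and QC samples, both
    regions), ``meta`` the :class:`SampleMeta`, ``blanks`` a blank-signal
    DataFrame for LOD computation, and ``truth`` the :class:`SimTruth`
    record of all realized parameters.
    """
    root = np.random.SeedSequence(cfg.seed)
    ss_meta, ss_plate, ss_dopa, ss_blank, ss_analytes, ss_block = root.spawn(6)
    rng_meta = np.random.default_rng(ss_meta)

    subjects = _make_subjects(cfg, rng_meta)

    # L+ assignment: independent of progression scores by construction
    rng_dopa = np.random.default_rng(ss_dopa)
    lplus = {
        sid: bool(rng_dopa.random() < cfg.frac_levodopa_positive)
        for sid, g in subjects["group"].items() if g != "CTRL"
    }

    # region sample rosters: putamen subjects are the first k of each group
    region_samples = {}
    for region, counts, plates in (
        ("cortex", cfg.n_cortex, [f"C{i + 1}" for i in range(cfg.n_plates_cortex)]),
        ("putamen", cfg.n_putamen, ["P1"]),
    ):
        rows = []
        for g in GROUPS:
            sel = subjects.index[subjects["group"] == g][: counts[g]]
            rows.extend(sel)
        if not rows:
            continue
        sub = subjects.loc[rows].copy()
        sub["region"] = region
        rng_plate = np.random.default_rng(ss_plate.spawn(1)[0]) if region == "cortex" \
            else np.random.default_rng(0)
        sub["plate_id"] = _assign_plates(sub["group"], plates, rng_plate).values
        sub.index = [f"{s}_{region[:3].upper()}" for s in rows]
        # QC repeats on every plate
        qc_rows = []
        for p in plates:
            for i in range(cfg.n_qc_per_plate):
                qc_rows.append({
                    "subject_id": f"QC_{p}", "group": "QC", "region": region,
                    "plate_id": p,
                })
        qc = pd.DataFrame(qc_rows,
                          index=[f"QC_{r['plate_id']}_{i + 1}" for i, r in
                                 enumerate(qc_rows)])
        region_samples[region] = pd.concat([sub, qc])

    meta_frame = pd.concat(region_samples.values())

    analyte_ids = (
        ["DOPA"]
        + list(cfg.named_analytes)
        + [f"LC_{i + 1:03d}" for i in range(cfg.n_analytes_lc)]
        + [f"FIA_{i + 1:03d}" for i in range(cfg.n_analytes_fia)]
    )
    n_lc_total = 1 + len(cfg.named_analytes) + cfg.n_analytes_lc
    methods = ["LC"] * n_lc_total + ["FIA"] * cfg.n_analytes_fia
    ann = pd.DataFrame({
        "method": methods,
        "analyte_type": "measured",
        "class_label": ["amine"] * n_lc_total + ["lipid"] * cfg.n_analytes_fia,
    }, index=pd.Index(analyte_ids, name="analyte_id"))

    # per-analyte parameters and RNG streams
    children = ss_analytes.spawn(len(analyte_ids))
    rng_param = np.random.default_rng(ss_blank)
    lo_s, hi_s = cfg.analyte_sigma_range
    log_mean = pd.Series(rng_param.normal(np.log(10.0), 1.0, len(analyte_ids)),
                         index=analyte_ids)
    log_sd = pd.Series(rng_param.uniform(lo_s, hi_s, len(analyte_ids)),
                       index=analyte_ids)
    log_sd["DOPA"] = 0.4
    expected_qc = pd.Series(np.exp(rng_param.normal(np.log(5.0), 1.0,
                                                    len(analyte_ids))),
                            index=analyte_ids).round(4)

    all_plates = sorted(meta_frame["plate_id"].unique())
    pf = pd.DataFrame(1.0, index=analyte_ids, columns=all_plates)
    cortex_plates = [p for p in all_plates if p.startswith("C")]
    for m_i, m in enumerate(analyte_ids):
        rng_m = np.random.default_rng(children[m_i].spawn(1)[0])
        for p in cortex_plates:
            pf.loc[m, p] = float(np.exp(rng_m.normal(0.0, cfg.plate_factor_sigma)))

    # covariate z-scores and score regressors, per region
    covariate_cols = ("age", "education", "bmi")
    z_cov = {}
    z_score = {}
    for region, sub in region_samples.items():
        subj = sub[sub["group"] != "QC"]
        z = pd.DataFrame(0.0, index=sub.index, columns=list(covariate_cols) + ["sexM"])
        for c in covariate_cols:
            v = subj[c].astype(float)
            sd = v.std(ddof=1)
            z.loc[subj.index, c] = (v.fillna(v.mean()) - v.mean()) / (sd if sd > 0 else 1)
        z.loc[subj.index, "sexM"] = (subj["sex"] == "M").astype(float) - 0.5
        z_cov[region] = z
        zs = pd.DataFrame(0.0, index=sub.index, columns=list(SCORES))
        pd_mask = subj["group"].isin(PD_GROUPS)
        for sc in SCORES:
            v = subj.loc[pd_mask, sc].astype(float)
            if v.notna().sum() >= 2 and v.std(ddof=1) > 0:
                zz = (v - v.mean()) / v.std(ddof=1)
                zs.loc[zz.index, sc] = zz.fillna(0.0)
        z_score[region] = zs

    # block-correlated residual component (optional, off by default)
    rng_block = np.random.default_rng(ss_block.spawn(1)[0])
    block_factor = None
    if cfg.block_size > 1 and cfg.block_rho > 0:
        n_blocks = int(np.ceil(len(analyte_ids) / cfg.block_size))
        block_factor = pd.DataFrame(
            rng_block.standard_normal((len(meta_frame), n_blocks)),
            index=meta_frame.index)

    values = pd.DataFrame(np.nan, index=meta_frame.index, columns=analyte_ids)
    for m_i, m in enumerate(analyte_ids):
        rng_m = np.random.default_rng(children[m_i])
        sd_m = log_sd[m]
        for region, sub in region_samples.items():
            eta = np.full(len(sub), log_mean[m])
            groups = sub["group"].values
            is_qc = groups == "QC"
            eps = rng_m.standard_normal(len(sub))
            if block_factor is not None:
                b = block_factor.loc[sub.index, m_i // cfg.block_size].values
                eps = (np.sqrt(1 - cfg.block_rho) * eps
                       + np.sqrt(cfg.block_rho) * b)
            scale = np.array([cfg.group_sigma_scale.get(g, 1.0) for g in groups])
            for g in GROUPS:
                eff = cfg.group_effects.get((m, g), 0.0)
                if eff:
                    eta[groups == g] += eff * sd_m
            # acute levodopa effect, by dementia status
            for i, sid in enumerate(sub["subject_id"]):
                g = groups[i]
                if g in PD_GROUPS and lplus.get(sid, False):
                    key = "PD-D" if g == "PD-D" else "PD-ND"
                    eta[i] += cfg.levodopa_effects.get((m, key), 0.0) * sd_m
            for c, eff in cfg.covariate_effects.items():
                eta += eff * sd_m * z_cov[region][c].values
            for sc in SCORES:
                eff = cfg.score_effects.get((m, sc), 0.0)
                if eff:
                    eta += eff * sd_m * z_score[region][sc].values
            if m == "DOPA":
                shift = np.array([
                    cfg.dopa_separation * sd_m
                    if (groups[i] in PD_GROUPS
                        and lplus.get(sub["subject_id"].iloc[i], False)) else 0.0
                    for i in range(len(sub))])
                eta += shift
            noise = np.where(is_qc, cfg.qc_cv * eps, sd_m * scale * eps)
            eta_qc = np.where(is_qc, log_mean[m], eta)
            x = np.exp(eta_qc + noise)
            x *= sub["plate_id"].map(pf.loc[m]).values
            values.loc[sub.index, m] = x

    # simulated LODs: per-analyte low quantile of subject values; blanks are
    # written so that 2 x median(blank) reproduces the LOD exactly
    subj_mask = meta_frame["group"] != "QC"
    if cfg.lod_censor_quantile > 0:
        lod = values[subj_mask].quantile(cfg.lod_censor_quantile,
                                         interpolation="lower")
    else:
        lod = pd.Series(0.0, index=analyte_ids)
    blank_rows = {}
    for j, mult in enumerate((0.8, 1.0, 1.25)):
        blank_rows[f"BLANK_{j + 1}"] = lod / 2.0 * mult
    blanks = pd.DataFrame(blank_rows).T
    blanks.index.name = "sample_id"
    censored = values.lt(lod, axis=1) & subj_mask.values[:, None]

    meta_out = meta_frame.copy()
    meta_out["dopa_level"] = values["DOPA"]
    table = AnalyteTable(values, ann)
    meta = SampleMeta(meta_out)
    truth = SimTruth(
        config=cfg, analyte_log_mean=log_mean, analyte_log_sd=log_sd,
        plate_factors=pf, lplus=lplus, lod=lod, censored=censored,
        expected_qc_conc=expected_qc,
        group_effects=dict(cfg.group_effects),
        levodopa_effects=dict(cfg.levodopa_effects),
        score_effects=dict(cfg.score_effects),
        covariate_effects=dict(cfg.covariate_effects),
    )
    return table, meta, blanks, truth


def simulate_null_pvalues(n_tests: int, seed) -> np.ndarray:
    """I.i.d. Uniform(0, 1] p-values for FDR / enrichment calibration."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    rng = np.random.default_rng(seed)
    return 1.0 - rng.random(n_tests)
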