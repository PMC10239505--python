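"""Raw analyte values -> analysis-ready standardized values.

The stage order is fixed and mirrors how targeted metabolomics data are
prepared for regression modeling:

1. linear quantification from QC medians (area ratio -> µM),
2. limit of detection (LOD = 2 x median blank signal) and group-wise
   sub-LOD filtering,
3. interpolation of exact zeros as half the minimal non-zero value,
4. metabolic-indicator computation (sums/ratios of metabolites),
5. plate median normalization (metabolites and indicators alike),
6. per-analyte Box-Cox transformation,
7. Tukey fencing of remote outliers (k = 3, values adjusted to the fence),
8. standardization to the control samples' mean and SD.

Cortex and putamen are processed independently throughout: group reference
medians, Box-Cox lambdas, fences, control statistics and the acute-levodopa
(DOPA) threshold are all region-wise. :func:`run_pipeline` enforces the
order; the individual operations validate their own preconditions (e.g.
Box-Cox refuses non-positive values, which can only mean a stage was
skipped).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import AnalyteTable, IndicatorDef, SampleMeta

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Quantification and LOD
# ---------------------------------------------------------------------------

def quantify_linear(table: AnalyteTable, qc_mask, expected_qc_conc) -> tuple[
        AnalyteTable, list[str]]:
    """Estimate concentrations linearly from QC medians.

    conc(s, m) = ratio(s, m) * expected_conc(m) / median_QC(ratio(., m)).
    Analytes without an expected concentration, or whose QC median is zero,
    pass through unchanged and are returned in the flag list. The same
    per-analyte factors are exposed via ``quantify_factors`` so that blank
    signals can be brought to the same scale before LOD computation.
    """
    qc_mask = pd.Series(qc_mask, index=table.values.index) \
        if not isinstance(qc_mask, pd.Series) else qc_mask
    if qc_mask.sum() < 1:
        raise PipelineError("quantify_linear requires at least one QC sample")
    factors = quantify_factors(table, qc_mask, expected_qc_conc)
    out = table.values * factors.reindex(table.analyte_ids).fillna(1.0)
    flagged = [m for m in table.analyte_ids if m not in factors.index]
    if flagged:
        logger.info("quantify_linear: %d analytes left as area ratios", len(flagged))
    return AnalyteTable(out, table.annotations), flagged


def quantify_factors(table: AnalyteTable, qc_mask, expected_qc_conc) -> pd.Series:
    """Per-analyte ratio->µM factors: expected_conc / median QC ratio.

    Unquantifiable analytes (no expected concentration, or QC median <= 0)
    are absent from the result.
    """
    qc_mask = pd.Series(qc_mask, index=table.values.index) \
        if not isinstance(qc_mask, pd.Series) else qc_mask
    factors = {}
    for m in table.analyte_ids:
        exp_c = expected_qc_conc.get(m) if expected_qc_conc is not None else None
        if exp_c is None or not np.isfinite(exp_c):
            continue
        qc_med = np.nanmedian(table.values.loc[qc_mask.values, m].to_numpy())
        if not np.isfinite(qc_med) or qc_med <= 0:
            continue
        factors[m] = float(exp_c) / qc_med
    return pd.Series(factors, dtype=float)


def compute_lod(blanks: pd.DataFrame, multiplier: float = 2.0) -> pd.Series:
    """LOD per analyte: ``multiplier`` x median blank signal (default 2x)."""
    if blanks.shape[0] < 1:
        raise PipelineError("compute_lod requires at least one blank sample")
    lod = multiplier * blanks.median(axis=0, skipna=True)
    return lod.dropna()


def filter_below_lod(table: AnalyteTable, lod: pd.Series, meta: SampleMeta,
                     max_fraction: float = 0.5) -> tuple[AnalyteTable, list[str]]:
    """Drop analytes with > ``max_fraction`` sub-LOD values in *every* group.

    QC samples are excluded from the group fractions; retained sub-LOD
    values are left untouched (they remain the best available estimates).
    Analytes without a blank-derived LOD are exempt.
    """
    subj = meta.subjects().index.intersection(table.values.index)
    groups = meta.frame.loc[subj, "group"]
    removed = []
    for m in table.analyte_ids:
        if m not in lod.index or not np.isfinite(lod[m]):
            continue
        v = table.values.loc[subj, m]
        below_all = True
        for g, idx in groups.groupby(groups).groups.items():
            vals = v.loc[idx].dropna()
            if len(vals) == 0:
                continue
            if (vals < lod[m]).mean() <= max_fraction:
                below_all = False
                break
        if below_all:
            removed.append(m)
    if removed:
        logger.info("filter_below_lod: removed %d analytes", len(removed))
    keep = [m for m in table.analyte_ids if m not in set(removed)]
    return table.subset_analytes(keep), removed


def interpolate_zeros(table: AnalyteTable) -> tuple[AnalyteTable, list[str]]:
    """Replace exact zeros by half the analyte's minimal non-zero value."""
    out = table.values.copy()
    flagged = []
    for m in table.analyte_ids:
        v = out[m]
        zeros = v == 0
        if not zeros.any():
            continue
        nonzero = v[(v > 0)]
        if len(nonzero) == 0:
            out[m] = np.nan
            flagged.append(m)
            continue
        out.loc[zeros, m] = nonzero.min() / 2.0
    return AnalyteTable(out, table.annotations), flagged


# ---------------------------------------------------------------------------
# Plate normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationRecord:
    """Per-analyte plate quotients and intermediate reference values."""

    quotients: pd.DataFrame      # analyte x plate (q_p)
    reference: pd.DataFrame      # samples x analytes (r_s, group-prescaled)
    warnings: list = field(default_factory=list)


def plate_normalize(table: AnalyteTable, meta: SampleMeta) -> tuple[
        AnalyteTable, NormalizationRecord]:
    """Median normalization of plate batch effects, leveraging all samples.

    Per analyte and per region: every sample value is first divided by the
    median of its own group (QC counts as a group), making all samples
    usable as plate references; each plate's quotient is the median of
    these references on the plate divided by the overall reference median;
    the normalized value is the raw value divided by its plate's quotient.

    Groups whose median is zero are excluded from the reference set for
    that analyte; a plate with no finite reference gets quotient 1.
    """
    samples = table.values.index
    if not samples.isin(meta.frame.index).all():
        raise PipelineError("plate_normalize: samples missing from metadata")
    info = meta.frame.loc[samples, ["group", "region", "plate_id"]]
    y = table.values.copy()
    plates_all = sorted(info["plate_id"].unique())
    quot = pd.DataFrame(np.nan, index=table.analyte_ids, columns=plates_all)
    ref = pd.DataFrame(np.nan, index=samples, columns=table.analyte_ids)
    warns: list[str] = []

    for region in info["region"].unique():
        rmask = info["region"] == region
        ridx = samples[rmask]
        groups = info.loc[ridx, "group"]
        plates = info.loc[ridx, "plate_id"]
        for m in table.analyte_ids:
            x = table.values.loc[ridx, m].to_numpy(dtype=float)
            finite = np.isfinite(x)
            r = np.full_like(x, np.nan)
            for g in groups.unique():
                gm = (groups == g).to_numpy()
                gv = x[gm & finite]
                if len(gv) == 0:
                    continue
                med = np.median(gv)
                if med == 0:
                    warns.append(f"{region}/{m}: group {g} median is 0; excluded")
                    continue
                r[gm] = x[gm] / med
            r_fin = r[np.isfinite(r)]
            if len(r_fin) == 0:
                warns.append(f"{region}/{m}: no finite reference values")
                for p in plates.unique():
                    quot.loc[m, p] = 1.0
                continue
            overall = np.median(r_fin)
            q_map = {}
            for p in plates.unique():
                pv = r[(plates == p).to_numpy() & np.isfinite(r)]
                if len(pv) == 0 or overall == 0:
                    warns.append(f"{region}/{m}: plate {p} has no reference; q=1")
                    q_map[p] = 1.0
                else:
                    q_map[p] = float(np.median(pv) / overall)
                quot.loc[m, p] = q_map[p]
            y.loc[ridx, m] = x / plates.map(q_map).to_numpy()
            ref.loc[ridx, m] = r
    for w in warns:
        logger.warning("plate_normalize: %s", w)
    return AnalyteTable(y, table.annotations), NormalizationRecord(quot, ref, warns)


# ---------------------------------------------------------------------------
# Indicators
# ---------------------------------------------------------------------------

def compute_indicators(table: AnalyteTable, defs: list[IndicatorDef]) -> AnalyteTable:
    """Compute sum/ratio metabolic indicators from metabolite values.

    Members absent from the table (e.g. filtered at the LOD stage) are
    dropped; an indicator with no remaining numerator member is all-missing.
    Ratios with a zero denominator sum are missing. Indicators are labeled
    ``calculated``; the acquisition method is FIA if any constituent is FIA
    (conservative FDR stratum), LC otherwise.
    """
    cols = {}
    ann_rows = []
    present = set(table.analyte_ids)
    for d in defs:
        num = [a for a in d.numerator if a in present]
        den = [a for a in d.denominator if a in present]
        if not num or (d.kind == "ratio" and not den):
            logger.warning("indicator %s: constituents filtered out; all-missing",
                           d.indicator_id)
            vals = pd.Series(np.nan, index=table.values.index)
            methods = ["LC"]
        else:
            num_sum = table.values[num].sum(axis=1, skipna=False)
            if d.kind == "sum":
                vals = num_sum
            else:
                den_sum = table.values[den].sum(axis=1, skipna=False)
                vals = num_sum / den_sum.replace(0.0, np.nan)
            methods = list(table.annotations.loc[num + den, "method"])
        cols[d.indicator_id] = vals
        ann_rows.append({
            "analyte_id": d.indicator_id,
            "method": "FIA" if "FIA" in methods else "LC",
            "analyte_type": "calculated",
            "class_label": "indicator",
        })
    values = pd.DataFrame(cols, index=table.values.index)
    ann = pd.DataFrame(ann_rows).set_index("analyte_id") if ann_rows else \
        pd.DataFrame(columns=["method", "analyte_type", "class_label"])
    return AnalyteTable(values, ann)


def append_indicators(table: AnalyteTable, indicators: AnalyteTable) -> AnalyteTable:
    values = pd.concat([table.values, indicators.values], axis=1)
    ann = pd.concat([table.annotations, indicators.annotations])
    return AnalyteTable(values, ann)


# ---------------------------------------------------------------------------
# Transformation
# ---------------------------------------------------------------------------

def boxcox_fit_transform(values, lam_bounds=(-3.0, 3.0), tol=1e-4):
    """Box-Cox transform with lambda maximizing the profile log-likelihood.

    The search is a bounded scalar minimization (golden-section/Brent) of
    the negative profile likelihood over ``lam_bounds``. Returns the
    transformed vector (missing entries preserved) and the fitted lambda;
    a constant vector has no defined lambda and comes back unchanged with
    ``lambda = nan``.
    """
    v = np.asarray(values, dtype=float)
    fin = np.isfinite(v)
    x = v[fin]
    if np.any(x <= 0):
        raise PipelineError(
            "boxcox_fit_transform: non-positive values (zero interpolation "
            "must run before transformation)")
    if len(x) < 2 or np.all(x == x[0]):
        return v.copy(), float("nan")

    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, x),
        bounds=lam_bounds, method="bounded",
        options={"xatol": tol})
    lam = float(res.x)
    out = np.full_like(v, np.nan)
    out[fin] = stats.boxcox(x, lmbda=lam)
    return out, lam


def tukey_fence(values, k: float = 3.0):
    """Adjust remote outliers to Tukey's fences Q1 - k*IQR / Q3 + k*IQR.

    Values are moved to the fence, not removed, preserving sample size
    while limiting the influence of extremes. Returns the adjusted vector
    and a record dict (fences and number of adjusted values).
    """
    v = np.asarray(values, dtype=float)
    fin = np.isfinite(v)
    if fin.sum() < 4:
        return v.copy(), {"lower": np.nan, "upper": np.nan, "n_adjusted": 0, "k": k}
    q1, q3 = np.quantile(v[fin], [0.25, 0.75])  # type-7 linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    out = v.copy()
    n_adj = int(np.sum((v[fin] < lo) | (v[fin] > hi)))
    out[fin] = np.clip(v[fin], lo, hi)
    return out, {"lower": float(lo), "upper": float(hi), "n_adjusted": n_adj, "k": k}


def standardize_to_controls(values, control_mask):
    """z = (v - mean(controls)) / sd(controls); flags degenerate analytes."""
    v = np.asarray(values, dtype=float)
    cm = np.asarray(control_mask, dtype=bool)
    ctrl = v[cm & np.isfinite(v)]
    if len(ctrl) < 3:
        return None, {"flag": "too_few_controls", "mean": np.nan, "sd": np.nan}
    mean, sd = float(np.mean(ctrl)), float(np.std(ctrl, ddof=1))
    if sd == 0:
        return None, {"flag": "zero_control_sd", "mean": mean, "sd": 0.0}
    return (v - mean) / sd, {"flag": None, "mean": mean, "sd": sd}


# ---------------------------------------------------------------------------
# Covariate imputation and levodopa classification
# ---------------------------------------------------------------------------

def impute_covariates(meta: SampleMeta, columns=("bmi", "education")) -> SampleMeta:
    """Fill missing BMI/education with the (group, sex)-conditional mean.

    Empty cells fall back to the group mean, then the overall mean; both
    fallbacks are logged. No other field is ever imputed.
    """
    df = meta.frame.copy()
    subj = df["group"] != "QC"
    for col in columns:
        if col not in df:
            continue
        miss = subj & df[col].isna()
        for sid in df.index[miss]:
            g, sex = df.at[sid, "group"], df.at[sid, "sex"]
            cell = df.loc[subj & (df["group"] == g) & (df["sex"] == sex), col].dropna()
            if len(cell):
                df.at[sid, col] = cell.mean()
                continue
            gcell = df.loc[subj & (df["group"] == g), col].dropna()
            if len(gcell):
                logger.info("impute %s for %s: empty (group, sex) cell, group mean",
                            col, sid)
                df.at[sid, col] = gcell.mean()
            else:
                logger.info("impute %s for %s: overall mean fallback", col, sid)
                df.at[sid, col] = df.loc[subj, col].dropna().mean()
    return SampleMeta(df)


@dataclass
class LevodopaStatus:
    """Acute levodopa presence per PD sample, with per-region thresholds."""

    flags: pd.Series        # PD sample id -> "L+" | "L-"
    thresholds: dict        # region -> 95% control quantile of DOPA

    def lplus_samples(self):
        return list(self.flags.index[self.flags == "L+"])


def classify_levodopa(dopa: pd.Series, meta: SampleMeta,
                      quantile: float = 0.95) -> LevodopaStatus:
    """Flag PD samples with DOPA above the controls' 95% quantile as L+.

    The threshold is region-wise; a tie goes to L- (strict inequality).
    Controls are never flagged.
    """
    flags = {}
    thresholds = {}
    frame = meta.frame
    for region in frame.loc[frame["group"] != "QC", "region"].unique():
        rmask = frame["region"] == region
        ctrl_idx = frame.index[rmask & (frame["group"] == "CTRL")]
        ctrl = dopa.reindex(ctrl_idx).dropna()
        if len(ctrl) == 0:
            raise PipelineError(f"classify_levodopa: no control DOPA in {region}")
        if len(ctrl) < 10:
            warnings.warn(f"classify_levodopa: only {len(ctrl)} control DOPA "
                          f"values in {region}", stacklevel=2)
        thr = float(np.quantile(ctrl, quantile))  # type-7
        thresholds[region] = thr
        pd_idx = frame.index[rmask & frame["group"].isin(("PD-CN", "PD-MCI", "PD-D"))]
        for sid in pd_idx:
            val = dopa.get(sid, np.nan)
            flags[sid] = "L+" if np.isfinite(val) and val > thr else "L-"
    return LevodopaStatus(pd.Series(flags, dtype=object), thresholds)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    lod_multiplier: float = 2.0
    below_lod_fraction: float = 0.5
    tukey_k: float = 3.0
    dopa_quantile: float = 0.95
    boxcox_bounds: tuple = (-3.0, 3.0)
    indicators_from_normalized: bool = False  # default: raw values, then normalize
    expected_qc_conc: pd.Series | None = None


@dataclass
class TransformRecord:
    table: pd.DataFrame  # per analyte: lambda, fences, control stats, flags


@dataclass
class ProcessedRegion:
    table: AnalyteTable            # standardized values (subject samples)
    normalization: NormalizationRecord
    transform: TransformRecord
    dropped: dict                  # stage -> list of analyte ids


@dataclass
class ProcessedData:
    regions: dict                  # region -> ProcessedRegion
    meta: SampleMeta               # covariate-imputed
    lstatus: LevodopaStatus
    lod: pd.Series


def run_pipeline(table: AnalyteTable, meta: SampleMeta, blanks: pd.DataFrame,
                 indicator_defs: list[IndicatorDef] | None = None,
                 config: PipelineConfig | None = None) -> ProcessedData:
    """Run the full fixed-order preprocessing chain, per brain region."""
    cfg = config or PipelineConfig()
    indicator_defs = indicator_defs or []

    qc_mask = meta.frame.loc[table.values.index, "group"] == "QC"
    if cfg.expected_qc_conc is not None:
        factors = quantify_factors(table, qc_mask, cfg.expected_qc_conc)
        table, _ = quantify_linear(table, qc_mask, cfg.expected_qc_conc)
        # blank signals move to the same scale so LODs stay comparable
        blanks = blanks * factors.reindex(blanks.columns).fillna(1.0)

    lod = compute_lod(blanks, cfg.lod_multiplier)

    regions = {}
    dopa_all = {}
    for region in meta.frame.loc[meta.frame["group"] != "QC", "region"].unique():
        ridx = meta.frame.index[meta.frame["region"] == region]
        rtable = table.subset_samples(table.values.index.intersection(ridx))
        rmeta = SampleMeta(meta.frame.loc[rtable.values.index])

        rtable, removed = filter_below_lod(rtable, lod, rmeta,
                                           cfg.below_lod_fraction)
        rtable, zero_flagged = interpolate_zeros(rtable)

        if cfg.indicators_from_normalized:
            rtable, norm = plate_normalize(rtable, rmeta)
            ind = compute_indicators(rtable, indicator_defs)
            ind, norm_ind = plate_normalize(ind, rmeta) if len(indicator_defs) \
                else (ind, None)
            combined = append_indicators(rtable, ind) if len(indicator_defs) else rtable
        else:
            ind = compute_indicators(rtable, indicator_defs)
            combined = append_indicators(rtable, ind) if len(indicator_defs) else rtable
            combined, norm = plate_normalize(combined, rmeta)

        # transformation happens on subject samples only (QC/blanks are
        # technical and excluded from model-facing statistics)
        subj_idx = rmeta.subjects().index
        sub = combined.subset_samples(subj_idx)
        ctrl_mask = rmeta.frame.loc[subj_idx, "group"] == "CTRL"

        dopa_all.update(sub.values["DOPA"].to_dict() if "DOPA" in sub.values else {})

        rows = []
        std_cols = {}
        flagged = []
        for m in sub.analyte_ids:
            v = sub.values[m].to_numpy(dtype=float)
            if np.isfinite(v).sum() < 10:
                flagged.append(m)
                rows.append({"analyte_id": m, "lambda": np.nan, "flag": "too_few"})
                continue
            t, lam = boxcox_fit_transform(v, cfg.boxcox_bounds)
            t, fence = tukey_fence(t, cfg.tukey_k)
            z, srec = standardize_to_controls(t, ctrl_mask.to_numpy())
            rows.append({
                "analyte_id": m, "lambda": lam,
                "fence_lower": fence["lower"], "fence_upper": fence["upper"],
                "n_adjusted": fence["n_adjusted"],
                "control_mean": srec["mean"], "control_sd": srec["sd"],
                "flag": srec["flag"],
            })
            if z is None:
                flagged.append(m)
            else:
                std_cols[m] = z
        std_values = pd.DataFrame(std_cols, index=subj_idx)
        std_table = AnalyteTable(std_values,
                                 combined.annotations.loc[list(std_cols)],
                                 nonnegative=False)
        regions[region] = ProcessedRegion(
            table=std_table,
            normalization=norm,
            transform=TransformRecord(pd.DataFrame(rows).set_index("analyte_id")),
            dropped={"below_lod": removed, "all_zero": zero_flagged,
                     "degenerate": flagged},
        )
        logger.info("preprocess %s: %d analytes in, %d retained", region,
                    len(table.analyte_ids), len(std_cols))

    meta_imp = impute_covariates(meta)
    lstatus = classify_levodopa(pd.Series(dopa_all), meta_imp, cfg.dopa_quantile)
    return ProcessedData(regions=regions, meta=meta_imp, lstatus=lstatus, lod=lod)
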