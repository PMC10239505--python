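"""Typed tables and strict readers/writers for the analysis pipeline.

All downstream stages operate on the in-memory containers defined here:
:class:`AnalyteTable` (samples x analytes with per-analyte annotations),
:class:`SampleMeta` (per-sample clinical/technical metadata),
:class:`IndicatorDef` (sum/ratio formulas for derived metabolic indicators)
and :class:`MetaboliteSetDB` (GMT-style metabolite sets).

Files are UTF-8 CSV or TSV; the delimiter is sniffed from the header line.
Missing-value tokens are "", "NA" and "NaN" (case-insensitive); any other
non-numeric cell in a numeric column is a hard error, so corrupt exports
fail loudly instead of silently shrinking the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("CTRL", "PD-CN", "PD-MCI", "PD-D")
"""Subject groups, in fixed display order (QC is a technical pseudo-group)."""

REGIONS = ("cortex", "putamen")

MISSING_TOKENS = frozenset({"", "na", "nan"})

#: Stable column order for result tables written by :func:`write_results`.
RESULT_COLUMNS = [
    "analyte_id", "set_id", "term", "region", "stratum",
    "beta", "se", "ci_low", "ci_high", "D_plus", "auc",
    "p", "q", "n_effective", "n_mapped", "n_pos", "n_neg",
    "mean_abs_beta", "converged",
]


class FormatError(ValueError):
    """Raised on malformed input files or invariant violations."""


def _sniff_sep(path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _parse_numeric(df: pd.DataFrame, context: str) -> pd.DataFrame:
    """Parse a frame of strings to floats, honoring the missing tokens."""
    def conv(cell):
        if isinstance(cell, str):
            if cell.strip().lower() in MISSING_TOKENS:
                return np.nan
            try:
                return float(cell)
            except ValueError:
                raise FormatError(
                    f"{context}: non-numeric cell {cell!r} "
                    "(allowed missing tokens: '', 'NA', 'NaN')"
                ) from None
        return np.nan if cell is None else float(cell)

    return df.map(conv).astype(float)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class AnalyteTable:
    """Samples x analytes matrix plus per-analyte annotations.

    ``values`` is a float DataFrame (rows = sample ids, columns = analyte
    ids); units are area ratios or µM depending on the pipeline stage.
    ``annotations`` is indexed by analyte id with columns ``method``
    (``LC`` or ``FIA``), ``analyte_type`` (``measured`` or ``calculated``)
    and free-text ``class_label``.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    #: raw abundances must be non-negative; transformed/standardized values
    #: (Box-Cox, z-scores) are exempt from that invariant
    nonnegative: bool = True

    def __post_init__(self):
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            raise FormatError("duplicated sample ids")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicated analyte ids")
        missing_ann = self.values.columns.difference(self.annotations.index)
        if len(missing_ann):
            raise FormatError(f"annotation missing for analytes: {sorted(missing_ann)[:5]}")
        self.annotations = self.annotations.loc[self.values.columns]
        bad_m = set(self.annotations["method"]) - {"LC", "FIA"}
        if bad_m:
            raise FormatError(f"unknown acquisition method(s): {bad_m}")
        bad_t = set(self.annotations["analyte_type"]) - {"measured", "calculated"}
        if bad_t:
            raise FormatError(f"unknown analyte type(s): {bad_t}")
        vals = self.values.to_numpy()
        if self.nonnegative and np.any(vals[np.isfinite(vals)] < 0):
            raise FormatError("negative analyte values are not allowed")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "AnalyteTable":
        return AnalyteTable(self.values.loc[list(sample_ids)], self.annotations,
                            self.nonnegative)

    def subset_analytes(self, analyte_ids) -> "AnalyteTable":
        return AnalyteTable(
            self.values[list(analyte_ids)], self.annotations.loc[list(analyte_ids)],
            self.nonnegative
        )


COMORBIDITIES = ("hyperlipidemia", "diabetes", "renal_insufficiency", "hypothyroidism")
SCORES = ("pd_duration", "updrs_m", "usslb", "mmse", "plaque_density", "tangle_density")

META_NUMERIC = ("age", "education", "bmi", "pmci", "storage", "dopa_level") + \
    COMORBIDITIES + SCORES


@dataclass
class SampleMeta:
    """Per-sample metadata: group, region, plate, covariates and scores.

    The frame is indexed by sample id. Group is one of CTRL/PD-CN/PD-MCI/
    PD-D/QC; region is cortex or putamen; ``pmci`` (post-mortem collection
    interval, hours) and ``storage`` (freezer storage, years) must be
    strictly positive for subject samples because the models use their
    logarithms. The study design has no PD-D putamen samples; a violation
    is only a warning so that non-study cohorts remain usable.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        if df.index.has_duplicates:
            raise FormatError("duplicated sample ids in metadata")
        bad = set(df["group"]) - set(GROUPS) - {"QC"}
        if bad:
            raise FormatError(f"unknown group label(s): {bad}")
        bad = set(df["region"]) - set(REGIONS)
        if bad:
            raise FormatError(f"unknown region label(s): {bad}")
        subj = df[df["group"] != "QC"]
        for col in ("pmci", "storage"):
            if col in subj and (subj[col].dropna() <= 0).any():
                raise FormatError(f"{col} must be > 0 (log-transformed in the models)")
        if "sex" in subj:
            bad = set(subj["sex"].dropna()) - {"M", "F"}
            if bad:
                raise FormatError(f"unknown sex label(s): {bad}")
        if ((df["group"] == "PD-D") & (df["region"] == "putamen")).any():
            warnings.warn("PD-D putamen samples present; the study design has none",
                          stacklevel=2)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def subjects(self, region: str | None = None) -> pd.DataFrame:
        """Non-QC rows, optionally restricted to one region."""
        df = self.frame[self.frame["group"] != "QC"]
        if region is not None:
            df = df[df["region"] == region]
        return df


@dataclass
class IndicatorDef:
    """A derived analyte: sum of metabolites, or ratio of two sums."""

    indicator_id: str
    kind: str  # "sum" | "ratio"
    numerator: list[str] = field(default_factory=list)
    denominator: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("sum", "ratio"):
            raise FormatError(f"indicator kind must be sum|ratio, got {self.kind!r}")
        if not self.numerator:
            raise FormatError(f"indicator {self.indicator_id}: empty numerator")
        if (self.kind == "sum") != (len(self.denominator) == 0):
            raise FormatError(
                f"indicator {self.indicator_id}: denominator must be empty iff kind=sum"
            )


@dataclass
class MetaboliteSetDB:
    """Metabolite sets (pathways); membership is many-to-many."""

    sets: dict[str, list[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __len__(self):
        return len(self.sets)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_analyte_table(path, annotation_path) -> AnalyteTable:
    """Read a samples x analytes CSV/TSV and its analyte annotation file.

    The data file has analyte ids in the header and sample ids in the first
    column. The annotation file maps analyte id -> method/analyte_type/
    class_label. Duplicated ids or missing annotations are hard errors.
    """
    sep = _sniff_sep(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(header) != len(set(header)):  # pandas would mangle these to A.1
        raise FormatError(f"{path}: duplicated analyte columns")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        raise FormatError(f"{path}: duplicated sample ids")
    values = _parse_numeric(raw, str(path))
    ann = read_annotations(annotation_path)
    logger.info("read %s: %d samples x %d analytes", path, *values.shape)
    return AnalyteTable(values, ann)


def read_annotations(path) -> pd.DataFrame:
    sep = _sniff_sep(path)
    ann = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"analyte_id", "method", "analyte_type"}
    if not required <= set(ann.columns):
        raise FormatError(f"{path}: annotation columns must include {sorted(required)}")
    if "class_label" not in ann.columns:
        ann["class_label"] = ""
    if ann["analyte_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated analyte ids in annotations")
    return ann.set_index("analyte_id")


def read_matrix(path) -> pd.DataFrame:
    """Read a plain numeric samples x analytes matrix (e.g. blank signals)."""
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    return _parse_numeric(raw, str(path))


def read_sample_meta(path) -> SampleMeta:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        if col in META_NUMERIC:
            out[col] = _parse_numeric(df[[col]], f"{path}:{col}")[col]
        else:
            out[col] = df[col].replace({t: None for t in ("", "NA", "NaN")})
    return SampleMeta(out)


def read_indicator_defs(path) -> list[IndicatorDef]:
    """Read indicator definitions: indicator_id, kind, numerator, denominator.

    Member lists use ``|`` as the within-cell separator.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    defs = []
    for _, row in df.iterrows():
        num = [a for a in row.get("numerator", "").split("|") if a]
        den = [a for a in row.get("denominator", "").split("|") if a]
        defs.append(IndicatorDef(row["indicator_id"], row["kind"], num, den))
    return defs


def read_gmt(path) -> MetaboliteSetDB:
    """Read metabolite sets in GMT format (set id, description, members...).

    Duplicate members within a set are collapsed (order preserved). Members
    absent from any analyte table are retained; filtering happens at
    mapping time.
    """
    sets: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            set_id, desc, *members = fields
            members = list(dict.fromkeys(m for m in members if m))
            if not members:
                raise FormatError(f"{path}:{lineno}: set {set_id!r} has no members")
            sets[set_id] = members
            names[set_id] = desc
    return MetaboliteSetDB(sets, names)


def write_gmt(db: MetaboliteSetDB, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, members in db.sets.items():
            fh.write("\t".join([set_id, db.names.get(set_id, set_id), *members]) + "\n")


# ---------------------------------------------------------------------------
# Result output
# ---------------------------------------------------------------------------

def write_results(results: pd.DataFrame, path) -> None:
    """Write a fit/set/AUC result table as CSV with a stable column order.

    Numeric values are written with 12 significant digits so that
    ``read_results(write_results(t)) == t`` within 1e-12 relative.
    """
    if results is None:
        raise ValueError("results must not be None")
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results[cols].to_csv(path, index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_analyte_table(table: AnalyteTable, path, annotation_path=None) -> None:
    table.values.to_csv(path, float_format="%.12g", index_label="sample_id")
    if annotation_path is not None:
        table.annotations.to_csv(annotation_path, index_label="analyte_id")


def write_sample_meta(meta: SampleMeta, path) -> None:
    meta.frame.to_csv(path, float_format="%.12g", index_label="sample_id")
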