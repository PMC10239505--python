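"""Covariate-adjusted metabolite-set enrichment (ChemRICH-style statistics).

Each metabolite set's member p-values — taken from any comparative model,
here the covariate-adjusted regressions — are tested against the uniform
distribution with a one-sided Kolmogorov-Smirnov statistic
D+ = max_i (i/n - p_(i)). Because the member p-values already come from
covariate-adjusted models, the set test inherits the adjustment, which
plain overrepresentation tests cannot do. Membership is many-to-many
(one measured analyte may be an unresolved mix of isoforms belonging to
several pathways); a configurable custom set of microbial metabolites can
be appended; only sets with at least four mapped members are tested, and
set-level FDR is controlled with q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MetaboliteSetDB
from .models import ModelError, qvalues

logger = logging.getLogger(__name__)

MIN_SET_SIZE = 4
EXACT_MAX_N = 10

#: The custom microbial-metabolite set appended when members are measured.
MICROBIAL_SET_ID = "MICROBIAL"


@dataclass
class MappedSet:
    set_id: str
    members: list[str]   # analytes present in the analyzed table

    @property
    def n_mapped(self) -> int:
        return len(self.members)


def map_sets(db: MetaboliteSetDB, analytes, microbial_members=None,
             min_size: int = MIN_SET_SIZE) -> list[MappedSet]:
    """Intersect set members with the analyzed analytes; drop small sets.

    ``microbial_members`` (e.g. indoles, 5-aminovaleric acid,
    trimethylamine N-oxide, para-cresol sulfate, secondary bile acids)
    defines an extra custom set appended before size filtering.
    """
    measured = set(analytes)
    if not measured or (len(db) == 0 and not microbial_members):
        raise ModelError("map_sets: empty set database or analyte list")
    all_sets = dict(db.sets)
    if microbial_members:
        all_sets[MICROBIAL_SET_ID] = list(dict.fromkeys(microbial_members))
    mapped = []
    n_dropped = 0
    for set_id, members in all_sets.items():
        hit = [m for m in dict.fromkeys(members) if m in measured]
        if len(hit) >= min_size:
            mapped.append(MappedSet(set_id, hit))
        else:
            n_dropped += 1
    logger.info("map_sets: %d sets retained, %d below size %d",
                len(mapped), n_dropped, min_size)
    return mapped


def ks_uniform_test(p_members, method: str = "auto") -> tuple[float, float]:
    """One-sided KS test of member p-values against Uniform(0, 1).

    D+ = max_i (i/n - p_(i)) over the sorted p-values (right-continuous
    ECDF convention for ties). Small member p-values push the ECDF above
    the uniform CDF, giving large D+ and a small set p-value. With
    ``method='auto'`` the tail is exact (Birnbaum-Tingey, via
    ``scipy.stats.ksone``) for n <= 10 and asymptotic exp(-2 n D+^2)
    above; ``'exact'``/``'asymptotic'`` force one computation.
    """
    p = np.sort(np.asarray(p_members, dtype=float))
    n = len(p)
    if n < MIN_SET_SIZE:
        raise ModelError(f"ks_uniform_test needs >= {MIN_SET_SIZE} members, got {n}")
    if np.any(p <= 0) or np.any(p > 1):
        raise ModelError("member p-values must lie in (0, 1]")
    d_plus = float(max(np.max(np.arange(1, n + 1) / n - p), 0.0))
    if method not in ("auto", "exact", "asymptotic"):
        raise ModelError(f"unknown method {method!r}")
    if method == "exact" or (method == "auto" and n <= EXACT_MAX_N):
        p_set = float(stats.ksone.sf(d_plus, n))
    else:
        p_set = float(np.exp(-2.0 * n * d_plus ** 2))
    p_set = float(np.clip(p_set, np.finfo(float).tiny, 1.0))
    return d_plus, p_set


def run_enrichment(fit: pd.DataFrame, db: MetaboliteSetDB, term: str,
                   region: str | None = None, microbial_members=None,
                   min_size: int = MIN_SET_SIZE) -> pd.DataFrame:
    """Set-level results for one coefficient: D+, p, q, and mean |beta|.

    Analytes mapped to a set but lacking a fitted p-value for the chosen
    term are excluded and the mapped size recounted before the size filter.
    """
    rows = fit[fit["term"] == term]
    if region is not None:
        rows = rows[rows["region"] == region]
    if rows.empty:
        raise ModelError(f"term {term!r} not present in the fit results")
    rows = rows.set_index("analyte_id")
    pvals = rows["p"]
    betas = rows["beta"]
    mapped = map_sets(db, list(pvals.index), microbial_members, min_size=1)
    out = []
    for ms in mapped:
        members = [m for m in ms.members if m in pvals.index]
        if len(members) < min_size:
            continue
        d_plus, p_set = ks_uniform_test(pvals.loc[members].to_numpy())
        out.append({
            "set_id": ms.set_id, "term": term,
            "D_plus": d_plus, "p": p_set,
            "n_mapped": len(members),
            "mean_abs_beta": float(betas.loc[members].abs().mean()),
        })
    if not out:
        raise ModelError("no set passed the size filter")
    df = pd.DataFrame(out)
    df["q"] = qvalues(df["p"].to_numpy())
    return df


def enrichment_matrix(fit: pd.DataFrame, db: MetaboliteSetDB, terms,
                      region: str | None = None,
                      microbial_members=None) -> pd.DataFrame:
    """Wide sets x terms matrix of (p, q, mean |beta|) for several terms."""
    pieces = []
    for term in terms:
        res = run_enrichment(fit, db, term, region, microbial_members)
        res = res.set_index("set_id")[["p", "q", "mean_abs_beta"]]
        res.columns = pd.MultiIndex.from_product([[term], res.columns])
        pieces.append(res)
    return pd.concat(pieces, axis=1)
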