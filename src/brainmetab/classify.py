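"""Univariate dementia discrimination: AUC with DeLong confidence intervals.

Each analyte's standardized value is scored as a classifier of dementia
among PD subjects (PD-D vs PD-CN/PD-MCI), overall and within the acute
levodopa strata (L+ only, L- only), since some discriminators — cortical
homocysteine being the motivating example — separate the classes only in
the acutely medicated state. AUC is the Mann-Whitney probability with ties
counted 1/2; its variance comes from DeLong's placement-value estimator,
and the 95% CI is auc +/- 1.96 SE clipped to [0, 1]. Orientation is
corrected so reported AUC >= 0.5.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .preprocess import ProcessedData

logger = logging.getLogger(__name__)

STRATA = ("all PD", "L+ only", "L- only")


class ClassifyError(ValueError):
    pass


def auc_delong(scores, labels) -> dict:
    """AUC and DeLong 95% CI for one score vector against binary labels."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    pos, neg = s[y == 1], s[y == 0]
    n1, n0 = len(pos), len(neg)
    if n1 == 0 or n0 == 0:
        raise ClassifyError("both classes must be present")
    # placement values: psi = 1 if pos > neg, 1/2 on ties
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    auc = float(psi.mean())
    if auc < 0.5:  # orientation correction
        auc = 1.0 - auc
        psi = 1.0 - psi
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = float(np.var(v10, ddof=1)) if n1 > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n0 > 1 else 0.0
    se = float(np.sqrt(s10 / n1 + s01 / n0))
    return {
        "auc": auc, "se": se,
        "ci_low": float(max(0.0, auc - 1.96 * se)),
        "ci_high": float(min(1.0, auc + 1.96 * se)),
        "n_pos": n1, "n_neg": n0,
    }


def best_discriminator(processed: ProcessedData, region: str = "cortex",
                       min_per_class: int = 3) -> pd.DataFrame:
    """Rank analytes by dementia AUC, per levodopa stratum.

    The dementia label is PD-D = 1 vs PD-CN/PD-MCI = 0 (MCI counts as
    non-demented). Strata with fewer than ``min_per_class`` subjects in
    either class are skipped with a log note. Ties in AUC break by
    narrower CI, then analyte id.
    """
    pr = processed.regions[region]
    meta = processed.meta.subjects(region)
    meta = meta.loc[meta.index.intersection(pr.table.values.index)]
    is_pd = meta["group"].isin(("PD-CN", "PD-MCI", "PD-D"))
    pd_meta = meta[is_pd]
    labels = (pd_meta["group"] == "PD-D").astype(int)
    lflags = processed.lstatus.flags.reindex(pd_meta.index)
    rows = []
    for stratum in STRATA:
        if stratum == "all PD":
            idx = pd_meta.index
        elif stratum == "L+ only":
            idx = pd_meta.index[lflags == "L+"]
        else:
            idx = pd_meta.index[lflags == "L-"]
        y = labels.loc[idx]
        if (y == 1).sum() < min_per_class or (y == 0).sum() < min_per_class:
            logger.info("best_discriminator: stratum %r skipped (<%d per class)",
                        stratum, min_per_class)
            continue
        for m in pr.table.analyte_ids:
            res = auc_delong(pr.table.values.loc[idx, m], y)
            res.update(analyte_id=m, stratum=stratum, region=region)
            rows.append(res)
    if not rows:
        raise ClassifyError("no stratum had enough subjects per class")
    df = pd.DataFrame(rows)
    df["ci_width"] = df["ci_high"] - df["ci_low"]
    df = df.sort_values(["stratum", "auc", "ci_width", "analyte_id"],
                        ascending=[True, False, True, True])
    return df.drop(columns="ci_width").reset_index(drop=True)
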