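"""Scoring fine-mapping output against simulation truth.

Coverage is the fraction of loci whose credible set contains the true
causal variant; alongside it the report carries the set-size distribution
(mean, median, nearest-rank 95% quantile) — the usual accuracy-vs-size
trade-off summary for credible-set methods.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from . import assoc
from .core import CredibleSet, GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = [
    "nearest_rank_quantile",
    "coverage",
    "stratify_by_provenance",
    "variance_explained_comparison",
]


def nearest_rank_quantile(values: Sequence[float], q: float) -> float:
    """Nearest-rank empirical quantile: the ceil(q*n)-th order statistic."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    if len(v) == 0:
        return np.nan
    k = max(1, math.ceil(q * len(v)))
    return float(v[k - 1])


def coverage(
    sets: Sequence[CredibleSet],
    causal_ids: Sequence[str],
    analyzed_ids: Sequence[set] | None = None,
) -> pd.Series:
    """One report row: causal coverage and set-size statistics.

    ``sets[i]`` is scored against ``causal_ids[i]``.  If ``analyzed_ids``
    is given and a causal id is absent from its locus' analyzed sites
    (e.g. removed by post-imputation QC), the locus counts as not covered
    and the casualty is logged — fine-mapping cannot recover a variant
    that is not in the data.
    """
    if len(sets) != len(causal_ids):
        raise ValueError("one causal id per credible set required")
    hits = []
    sizes = []
    for i, (cs, causal) in enumerate(zip(sets, causal_ids)):
        if analyzed_ids is not None and causal not in analyzed_ids[i]:
            logger.info("locus %d: causal %s absent from analyzed sites", i, causal)
            hits.append(False)
        else:
            hits.append(causal in cs.members)
        cs.contains_causal = hits[-1]
        sizes.append(cs.size)
    sizes_arr = np.asarray(sizes, dtype=np.float64)
    return pd.Series(
        {
            "coverage": float(np.mean(hits)),
            "n_loci": len(sets),
            "mean_set_size": float(sizes_arr.mean()),
            "median_set_size": float(np.median(sizes_arr)),
            "q95_set_size": nearest_rank_quantile(sizes_arr, 0.95),
        }
    )


def stratify_by_provenance(
    sets: Sequence[CredibleSet],
    causal_ids: Sequence[str],
    causal_genotyped: Sequence[bool],
) -> pd.DataFrame:
    """Coverage computed separately for genotyped vs imputed causal sites.

    Mirrors the array-vs-imputed contrast: when the causal variant itself
    was genotyped on the array its dosages carry no imputation error, so
    its stratum should show higher coverage.  An empty stratum is emitted
    with n = 0 and NaN coverage.
    """
    if not (len(sets) == len(causal_ids) == len(causal_genotyped)):
        raise ValueError("sets, causal_ids and flags must align")
    rows = {}
    flags = np.asarray(causal_genotyped, dtype=bool)
    for label, mask in (("genotyped", flags), ("imputed", ~flags)):
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            logger.warning("stratum %r is empty", label)
            rows[label] = pd.Series(
                {
                    "coverage": np.nan,
                    "n_loci": 0,
                    "mean_set_size": np.nan,
                    "median_set_size": np.nan,
                    "q95_set_size": np.nan,
                }
            )
        else:
            rows[label] = coverage(
                [sets[i] for i in idx], [causal_ids[i] for i in idx]
            )
    return pd.DataFrame(rows).T


def variance_explained_comparison(
    arms: dict[str, GenotypeDataset], y, causal_id: str
) -> pd.Series:
    """Regression r^2 of the phenotype on the causal site, per dataset arm.

    Imputation error attenuates the causal dosage, so arms with poorer
    imputation explain less of the phenotypic variance.  If QC removed the
    causal site from an arm the value is NaN (flagged missing).
    """
    out = {}
    for name, data in arms.items():
        try:
            idx = data.site_index(causal_id)
        except KeyError:
            logger.warning("arm %r: causal site %s absent (QC casualty)", name, causal_id)
            out[name] = np.nan
            continue
        yv = assoc._phenotype_values(y)
        *_, r2, _ = assoc.ols_single(data.dosages[:, idx], yv)
        out[name] = r2
    return pd.Series(out)
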