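"""Array-masking, haplotype-copying imputation, info scores, and QC.

Emulates the genotyping-array -> imputation-server path: keep only the
"array" sites, then fill in the remaining reference-panel sites with
posterior-mean dosages from a Li-Stephens haplotype-copying HMM run
against a reference panel.  Imputation accuracy is controlled by the
reference panel's size and its divergence from the study population —
the experimental knobs that stand in for the choice of a large, matched
reference (HRC-like) vs a smaller, more heterogeneous one (1000G-like).

Phasing is deliberately bypassed: in simulation the target's true
haplotypes are known, and the HMM runs on each one directly, isolating
imputation error from phasing error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .core import GenotypeDataset, HaplotypePanel, SITE_COLUMNS

__all__ = [
    "QCConfig",
    "mask_to_array",
    "impute_li_stephens",
    "info_score",
    "hwe_exact_p",
    "apply_qc",
    "intersect_datasets",
]


def mask_to_array(truth: GenotypeDataset, array_site_ids) -> GenotypeDataset:
    """Restrict a dataset to the sites present on the genotyping array."""
    array_site_ids = list(array_site_ids)
    if not array_site_ids:
        raise ValueError("array site set is empty: nothing to impute from")
    known = set(truth.site_ids)
    unknown = [s for s in array_site_ids if s not in known]
    if unknown:
        raise KeyError(f"array site ids not in dataset: {unknown}")
    keep = np.isin(truth.site_ids, array_site_ids)
    out = truth.subset_sites(keep)
    sites = out.sites.copy()
    sites["genotyped"] = True
    sites["info"] = 1.0
    out.sites = sites
    return out


@njit(cache=True)
def _ls_posterior_alleles(ref, targets, observed, obs_mask, rho, mismatch):  # pragma: no cover
    """Posterior-mean allele per (target haplotype, site) under Li-Stephens.

    ref:      (H, M) reference alleles, float64 in {0,1}
    targets:  unused placeholder kept for shape clarity
    observed: (T, M) target alleles, float64 (only obs_mask sites are used)
    obs_mask: (M,) 1.0 where the site is on the array
    rho:      (M-1,) switch probability per adjacent-site interval
    mismatch: emission error rate at observed sites
    """
    H, M = ref.shape
    T = observed.shape[0]
    out = np.empty((T, M))
    alpha = np.empty((M, H))
    e = np.empty(H)
    for t in range(T):
        # forward, normalized each step
        for m in range(M):
            if obs_mask[m] > 0.5:
                o = observed[t, m]
                for j in range(H):
                    e[j] = (1.0 - mismatch) if ref[j, m] == o else mismatch
            else:
                for j in range(H):
                    e[j] = 1.0
            if m == 0:
                s = 0.0
                for j in range(H):
                    alpha[0, j] = e[j]
                    s += e[j]
                for j in range(H):
                    alpha[0, j] /= s
            else:
                r = rho[m - 1]
                s = 0.0
                for j in range(H):
                    v = e[j] * ((1.0 - r) * alpha[m - 1, j] + r / H)
                    alpha[m, j] = v
                    s += v
                for j in range(H):
                    alpha[m, j] /= s
        # backward, combined with alpha on the fly
        beta = np.ones(H)
        for m in range(M - 1, -1, -1):
            s = 0.0
            dose = 0.0
            for j in range(H):
                g = alpha[m, j] * beta[j]
                s += g
                dose += g * ref[j, m]
            out[t, m] = dose / s
            if m > 0:
                if obs_mask[m] > 0.5:
                    o = observed[t, m]
                    for j in range(H):
                        e[j] = (1.0 - mismatch) if ref[j, m] == o else mismatch
                else:
                    for j in range(H):
                        e[j] = 1.0
                r = rho[m - 1]
                tot = 0.0
                for j in range(H):
                    e[j] = e[j] * beta[j]
                    tot += e[j]
                sb = 0.0
                for j in range(H):
                    beta[j] = (1.0 - r) * e[j] + r * tot / H
                    sb += beta[j]
                for j in range(H):
                    beta[j] /= sb
    return out


def impute_li_stephens(
    array_data: GenotypeDataset,
    reference: HaplotypePanel,
    mismatch_rate: float = 0.005,
    switch_rate: float = 1e-6,
) -> GenotypeDataset:
    """Impute all reference-panel sites from array genotypes.

    Each of the target's two true haplotypes is modelled as a mosaic of
    reference haplotypes: transitions switch copying templates with
    probability ``1 - exp(-switch_rate * distance)`` per interval, and
    emissions allow a ``mismatch_rate`` copying error at observed (array)
    sites.  Unobserved sites get the posterior-mean reference allele;
    the diploid dosage is the sum over the two haplotypes.  Array sites
    keep their hard dosages.  Deterministic given its inputs.
    """
    if array_data.haplotypes is None:
        raise ValueError(
            "array_data must carry true haplotypes (simulated datasets do); "
            "phasing is bypassed by design"
        )
    if reference.n_haplotypes < 4:
        raise ValueError("reference panel must have at least 4 haplotypes")
    ref_ids = list(reference.site_ids)
    ref_index = {s: i for i, s in enumerate(ref_ids)}
    missing = [s for s in array_data.site_ids if s not in ref_index]
    if missing:
        raise KeyError(f"array sites absent from reference panel: {missing}")

    M = reference.n_sites
    obs_mask = np.zeros(M)
    observed = np.zeros((array_data.haplotypes.shape[0], M))
    for k, s in enumerate(array_data.site_ids):
        i = ref_index[s]
        obs_mask[i] = 1.0
        observed[:, i] = array_data.haplotypes[:, k]

    dist = np.diff(reference.positions).astype(np.float64)
    rho = 1.0 - np.exp(-switch_rate * dist)
    post = _ls_posterior_alleles(
        reference.alleles.astype(np.float64),
        np.empty((0, 0)),
        observed,
        obs_mask,
        rho,
        float(mismatch_rate),
    )
    dosages = post[0::2] + post[1::2]

    # array sites keep their hard calls
    arr_cols = np.array([ref_index[s] for s in array_data.site_ids])
    dosages[:, arr_cols] = array_data.dosages
    dosages = np.clip(dosages, 0.0, 2.0)

    p = dosages.mean(axis=0) / 2.0
    genotyped = obs_mask > 0.5
    info = np.array(
        [
            1.0 if genotyped[m] else info_score(dosages[:, m], p[m])
            for m in range(M)
        ]
    )
    sites = pd.DataFrame(
        {
            "id": reference.site_ids,
            "position": reference.positions,
            "maf": np.minimum(p, 1 - p),
            "genotyped": genotyped,
            "info": info,
            "hwe_p": np.nan,
            "missing_rate": 0.0,
        },
        columns=SITE_COLUMNS,
    )
    return GenotypeDataset(dosages, array_data.sample_ids, sites)


def info_score(dosages: np.ndarray, allele_freq: float) -> float:
    """IMPUTE/MaCH-style info: observed dosage variance / 2p(1-p), clipped.

    Hard genotypes at Hardy-Weinberg proportions score ~1; dosages shrunk
    to the allele-frequency prior (no information) score 0.  A monomorphic
    site has no defined score and returns NaN, which QC treats as a fail.
    """
    if not 0.0 < allele_freq < 1.0:
        return np.nan
    expected = 2.0 * allele_freq * (1.0 - allele_freq)
    observed = float(np.var(np.asarray(dosages, dtype=np.float64)))
    return float(np.clip(observed / expected, 0.0, 1.0))


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Sums the probabilities of all heterozygote counts (conditional on the
    allele counts) no more probable than the observed one.
    """
    n_rare_hom = min(n_hom1, n_hom2)
    n_common_hom = max(n_hom1, n_hom2)
    n = n_het + n_hom1 + n_hom2
    rare = 2 * n_rare_hom + n_het
    if n == 0 or rare == 0:
        return 1.0

    # unnormalized probabilities over all possible het counts of same parity
    het_min = rare % 2
    hets = np.arange(het_min, rare + 1, 2)
    logp = np.zeros(len(hets))
    from scipy.special import gammaln

    common = 2 * n - rare
    for i, h in enumerate(hets):
        rh = (rare - h) // 2
        ch = n - h - rh
        logp[i] = (
            h * np.log(2.0)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(rh + 1)
            - gammaln(ch + 1)
        )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = np.flatnonzero(hets == n_het)
    if obs.size == 0:  # inconsistent counts
        return 1.0
    p_obs = probs[obs[0]]
    return float(min(1.0, probs[probs <= p_obs + 1e-12].sum()))


@dataclass
class QCConfig:
    """Variant QC thresholds.

    Defaults follow standard post-imputation cleaning: MAF >= 0.01, HWE
    exact P >= 1e-6, missingness <= 5% (10% is typical for sequence data),
    and imputation info >= 0.8 (a stringent choice; 0.3 is the permissive
    alternative used by some cohorts).
    """

    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    max_missing: float = 0.05
    info_min: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 <= self.hwe_p_min <= 1.0:
            raise ValueError("hwe_p_min must be in [0, 1]")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")
        if not 0.0 <= self.info_min <= 1.0:
            raise ValueError("info_min must be in [0, 1]")


def apply_qc(
    data: GenotypeDataset, qc: QCConfig | None = None
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Apply MAF / HWE / missingness / info filters; return survivors + log.

    All filters are evaluated on the input dataset and the union of
    failures removed, so the outcome is independent of filter order.
    HWE uses the exact test on hard-called (rounded) genotypes.  The log
    has one row per filter with the number of sites it flags (a site can
    be flagged by several) plus a ``removed_total`` row.
    """
    if qc is None:
        qc = QCConfig()
    data = data.recompute_maf()
    maf = data.sites["maf"].to_numpy()
    info = data.sites["info"].to_numpy(dtype=np.float64)
    miss = data.sites["missing_rate"].to_numpy(dtype=np.float64)

    hard = np.rint(data.dosages).astype(np.int64)
    hwe_p = np.empty(data.n_sites)
    for m in range(data.n_sites):
        g = hard[:, m]
        hwe_p[m] = hwe_exact_p(
            int(np.sum(g == 1)), int(np.sum(g == 0)), int(np.sum(g == 2))
        )

    fail_maf = maf < qc.maf_min
    fail_hwe = hwe_p < qc.hwe_p_min
    fail_miss = miss > qc.max_missing
    fail_info = np.isnan(info) | (info < qc.info_min)
    fail_any = fail_maf | fail_hwe | fail_miss | fail_info

    log = pd.DataFrame(
        {
            "filter": ["maf", "hwe", "missingness", "info", "removed_total"],
            "n_removed": [
                int(fail_maf.sum()),
                int(fail_hwe.sum()),
                int(fail_miss.sum()),
                int(fail_info.sum()),
                int(fail_any.sum()),
            ],
        }
    )
    if fail_any.all():
        raise ValueError("QC removed every site; fine-mapping impossible")
    out = data.subset_sites(~fail_any)
    sites = out.sites.copy()
    sites["hwe_p"] = hwe_p[~fail_any]
    out.sites = sites
    return out, log


def intersect_datasets(*datasets: GenotypeDataset) -> list[GenotypeDataset]:
    """Restrict two or more datasets to their shared sites (by id).

    Output site order follows the first dataset.  Dosages are untouched;
    this is how arms derived from the same truth are made comparable.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets to intersect")
    shared = set(datasets[0].site_ids)
    for d in datasets[1:]:
        shared &= set(d.site_ids)
    if not shared:
        raise ValueError("datasets share no sites")
    order = [s for s in datasets[0].site_ids if s in shared]
    return [d.subset_site_ids(order) for d in datasets]
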