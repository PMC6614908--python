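"""Core data containers shared across the package.

The containers mirror the objects that flow through a fine-mapping study:
phased haplotype panels (the ground-truth population and the imputation
reference), diploid genotype datasets (hard or dosage calls with per-site
QC metadata), simulated phenotypes with their hidden truth, and the
credible sets / reports produced by the fine-mapping methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypePanel",
    "GenotypeDataset",
    "PhenotypeVector",
    "AssocResult",
    "LDStats",
    "BayesFactorSet",
    "CredibleSet",
    "ConditionalResult",
]


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes at biallelic sites.

    Parameters
    ----------
    alleles
        ``(H, M)`` matrix of 0/1 alleles; rows are haplotypes, columns sites.
    positions
        1-based base-pair coordinates, strictly increasing.
    site_ids
        Unique string identifier per site.
    """

    alleles: np.ndarray
    positions: np.ndarray
    site_ids: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(np.asarray(self.alleles, dtype=np.uint8))
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (haplotypes x sites) matrix")
        h, m = self.alleles.shape
        if len(self.positions) != m or len(self.site_ids) != m:
            raise ValueError("positions/site_ids length must match number of sites")
        if m > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if len(set(self.site_ids)) != m:
            raise ValueError("site_ids must be unique")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be binary")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Frequency of the '1' allele at each site."""
        return self.alleles.mean(axis=0)

    def site_index(self, site_id: str) -> int:
        idx = np.flatnonzero(self.site_ids == site_id)
        if idx.size == 0:
            raise KeyError(f"unknown site id: {site_id!r}")
        return int(idx[0])

    def subset_sites(self, mask_or_idx) -> "HaplotypePanel":
        idx = np.asarray(mask_or_idx)
        return HaplotypePanel(
            self.alleles[:, idx], self.positions[idx], self.site_ids[idx]
        )


SITE_COLUMNS = ["id", "position", "maf", "genotyped", "info", "hwe_p", "missing_rate"]


@dataclass
class GenotypeDataset:
    """Per-sample dosages plus per-site metadata.

    ``dosages`` is an ``(N, M)`` real matrix in [0, 2] (hard genotypes for
    sequenced/array sites, posterior-mean dosages for imputed ones).
    ``sites`` is a DataFrame with columns ``id, position, maf, genotyped,
    info, hwe_p, missing_rate``.  ``haplotypes`` optionally carries the true
    phased alleles (2N x M) when the dataset came from a simulated panel;
    the imputation emulator uses them as the phasing-free truth.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    sites: pd.DataFrame
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.ascontiguousarray(np.asarray(self.dosages, dtype=np.float64))
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match sample count")
        if len(self.sites) != m:
            raise ValueError("sites table must have one row per site")
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"sites table missing columns: {missing}")
        if self.dosages.size and (self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")
        self.sites = self.sites.reset_index(drop=True)
        if self.haplotypes is not None:
            self.haplotypes = np.ascontiguousarray(
                np.asarray(self.haplotypes, dtype=np.uint8)
            )
            if self.haplotypes.shape != (2 * n, m):
                raise ValueError("haplotypes must have shape (2N, M)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def site_ids(self) -> np.ndarray:
        return self.sites["id"].to_numpy(dtype=object)

    def site_index(self, site_id: str) -> int:
        idx = np.flatnonzero(self.site_ids == site_id)
        if idx.size == 0:
            raise KeyError(f"unknown site id: {site_id!r}")
        return int(idx[0])

    def allele_freqs(self) -> np.ndarray:
        """'1'-allele frequency implied by mean dosage."""
        return self.dosages.mean(axis=0) / 2.0

    def recompute_maf(self) -> "GenotypeDataset":
        p = self.allele_freqs()
        sites = self.sites.copy()
        sites["maf"] = np.minimum(p, 1 - p)
        return replace(self, sites=sites)

    def subset_sites(self, mask_or_idx) -> "GenotypeDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        haps = self.haplotypes[:, idx] if self.haplotypes is not None else None
        return GenotypeDataset(
            self.dosages[:, idx],
            self.sample_ids,
            self.sites.iloc[idx].reset_index(drop=True),
            haplotypes=haps,
        )

    def subset_site_ids(self, ids: Sequence[str]) -> "GenotypeDataset":
        idx = [self.site_index(s) for s in ids]
        return self.subset_sites(np.asarray(idx, dtype=np.int64))


@dataclass
class PhenotypeVector:
    """Simulated trait values with the hidden generating truth."""

    values: np.ndarray
    causal_ids: list[str]
    true_betas: np.ndarray
    h2_target: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.true_betas = np.asarray(self.true_betas, dtype=np.float64)
        if not 0.0 <= self.h2_target < 1.0:
            raise ValueError("h2_target must be in [0, 1)")
        if len(self.causal_ids) != len(self.true_betas):
            raise ValueError("one effect per causal site required")


@dataclass
class AssocResult:
    """Single-SNP association scan output, aligned to the dataset's sites.

    ``order`` ranks sites by association strength: ascending p-value, ties
    broken by descending |t| then by position.  Zero-variance sites carry
    NaN statistics and are excluded from the ranking.
    """

    site_ids: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    r2: np.ndarray
    intercept: np.ndarray
    n_used: int
    order: np.ndarray  # indices into site_ids, best first

    def ranked_ids(self) -> np.ndarray:
        return self.site_ids[self.order]

    def top_id(self) -> str:
        return str(self.site_ids[self.order[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.site_ids,
                "beta": self.beta,
                "se": self.se,
                "t_stat": self.t_stat,
                "p_value": self.p_value,
                "r2": self.r2,
                "intercept": self.intercept,
            }
        )


@dataclass
class LDStats:
    """Two-locus linkage disequilibrium summary."""

    d: float
    d_prime: float
    r2: float
    hap_freqs: np.ndarray  # [f_AB, f_Ab, f_aB, f_ab]; A/B = '1' alleles

    def __post_init__(self) -> None:
        self.hap_freqs = np.asarray(self.hap_freqs, dtype=np.float64)
        if self.hap_freqs.shape != (4,):
            raise ValueError("hap_freqs must have 4 entries")


@dataclass
class BayesFactorSet:
    """Per-site log10 Bayes factors of a single-SNP model vs the null."""

    site_ids: np.ndarray
    log10_bf: np.ndarray
    W: float
    model: str = "wakefield_abf"

    def __post_init__(self) -> None:
        self.log10_bf = np.asarray(self.log10_bf, dtype=np.float64)
        if not np.all(np.isfinite(self.log10_bf)):
            raise ValueError("log10 Bayes factors must be finite")


@dataclass
class CredibleSet:
    """A 95% (by default) credible/confidence set of candidate causal SNPs.

    ``evidence`` is method-specific: rank p-values for the J-test,
    per-SNP posterior probabilities (PPA) for the Bayes-factor method, and
    MCMC top-variant counts for the sampler-based method.
    """

    method: str
    level: float
    members: list[str]
    evidence: np.ndarray
    contains_causal: bool | None = None

    def __post_init__(self) -> None:
        if self.method not in {"jtest", "ppa", "mcmc_count"}:
            raise ValueError(f"unknown method: {self.method}")
        if not self.members:
            raise ValueError("credible set must be non-empty")
        self.evidence = np.asarray(self.evidence, dtype=np.float64)

    @property
    def size(self) -> int:
        return len(self.members)

    def __contains__(self, site_id: str) -> bool:
        return site_id in self.members


@dataclass
class ConditionalResult:
    """Outcome of a multi-signal conditional analysis."""

    signals: list[str]
    rounds: list[dict]
    method: str
    threshold: float

    @property
    def n_signals(self) -> int:
        return len(self.signals)
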