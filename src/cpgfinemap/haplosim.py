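"""Haplotype-panel and diploid-population simulators.

Real cohorts provide phased haplotypes with block-structured local LD; this
module generates synthetic stand-ins with the two properties downstream
fine-mapping actually exercises: (i) pairwise LD that decays with physical
distance (founder-mosaic generator) and (ii) exact small-locus haplotype
configurations such as a missing two-locus haplotype class, which forces
|D'| = 1 (explicit haplotype-frequency tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import GenotypeDataset, HaplotypePanel, SITE_COLUMNS

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "build_panel_mosaic",
    "build_panel_from_haplotype_table",
    "pair_into_diploids",
]


@dataclass
class ScenarioConfig:
    """Parameters for a simulated locus.

    The mosaic generator copies each output haplotype from a small pool of
    founder haplotypes, switching founders at rate ``recomb_rate`` per base
    pair and flipping alleles at rate ``mutation_rate`` per site.  Fewer
    founders and lower recombination give longer shared blocks, i.e.
    stronger local LD.
    """

    n_samples: int = 1366
    n_sites: int = 120
    causal_id: str | None = None
    causal_maf_min: float = 0.05
    n_founders: int = 12
    recomb_rate: float = 2e-6  # per bp, founder-switch probability scale
    mutation_rate: float = 0.002  # per site, allele flip probability
    region_length: int = 200_000
    n_haplotypes: int | None = None  # default 2 * n_samples
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.causal_maf_min <= 0.5:
            raise ValueError("causal_maf_min must be in (0, 0.5]")
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")


def _founder_haplotypes(rng: np.random.Generator, k: int, m: int) -> np.ndarray:
    """Founders with per-site allele frequencies drawn from a U-shaped law."""
    freqs = rng.beta(0.8, 0.8, size=m)
    founders = (rng.random((k, m)) < freqs).astype(np.uint8)
    return founders


def build_panel_mosaic(config: ScenarioConfig) -> HaplotypePanel:
    """Generate a haplotype panel by founder-copying with recombination.

    Each output haplotype is a mosaic of the founder pool: between adjacent
    sites it switches to a uniformly chosen founder with probability
    ``1 - exp(-recomb_rate * distance)``; mutation flips alleles
    independently at ``mutation_rate``.  Monomorphic sites are dropped
    (logged), so the returned panel may have fewer than ``n_sites`` sites.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_sites
    h = config.n_haplotypes if config.n_haplotypes is not None else 2 * config.n_samples

    positions = np.sort(
        rng.choice(np.arange(1, config.region_length + 1), size=m, replace=False)
    )
    founders = _founder_haplotypes(rng, config.n_founders, m)
    if np.all(founders == founders[0]):
        raise ValueError(
            "degenerate config: all founder haplotypes identical "
            "(increase n_founders or check mutation/frequency settings)"
        )

    # Founder index per (haplotype, site) via segment labelling: a switch
    # between sites j and j+1 starts a new segment with a fresh founder.
    dist = np.diff(positions).astype(np.float64)
    switch_p = 1.0 - np.exp(-config.recomb_rate * dist)
    switches = rng.random((h, m - 1)) < switch_p[None, :]
    seg = np.zeros((h, m), dtype=np.int64)
    seg[:, 1:] = np.cumsum(switches, axis=1)
    founder_draws = rng.integers(0, config.n_founders, size=(h, m))
    founder_idx = np.take_along_axis(founder_draws, seg, axis=1)
    alleles = founders[founder_idx, np.arange(m)[None, :]]

    if config.mutation_rate > 0:
        flips = rng.random((h, m)) < config.mutation_rate
        alleles = np.where(flips, 1 - alleles, alleles).astype(np.uint8)

    freq = alleles.mean(axis=0)
    keep = (freq > 0) & (freq < 1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("build_panel_mosaic: dropped %d monomorphic sites", n_dropped)
    alleles = alleles[:, keep]
    positions = positions[keep]
    if alleles.shape[1] < 2:
        raise ValueError("fewer than 2 polymorphic sites produced; enlarge the panel")
    site_ids = np.array([f"snp{p}" for p in positions], dtype=object)
    return HaplotypePanel(alleles, positions, site_ids)


def build_panel_from_haplotype_table(
    freqs: dict[tuple[int, ...], float] | pd.DataFrame,
    n_haplotypes: int,
    seed: int = 0,
    mode: str = "sample",
    positions: np.ndarray | None = None,
    site_ids: np.ndarray | None = None,
) -> HaplotypePanel:
    """Realize a panel from an explicit haplotype-frequency table.

    ``freqs`` maps allele tuples (one 0/1 entry per site) to frequencies
    summing to 1 (a DataFrame with allele columns plus a ``freq`` column is
    also accepted).  ``mode='sample'`` draws counts from a multinomial;
    ``mode='exact'`` uses largest-remainder rounding to hit integer counts.
    Haplotype classes absent from the table get frequency 0 — omitting one
    of the four two-locus classes is how a |D'| = 1 pair is constructed.
    """
    if isinstance(freqs, pd.DataFrame):
        allele_cols = [c for c in freqs.columns if c != "freq"]
        freqs = {
            tuple(int(v) for v in row[allele_cols]): float(row["freq"])
            for _, row in freqs.iterrows()
        }
    haps = list(freqs.keys())
    p = np.array([freqs[hp] for hp in haps], dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("haplotype frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"haplotype frequencies must sum to 1 (got {p.sum():.12g})")
    m = len(haps[0])
    if any(len(hp) != m for hp in haps):
        raise ValueError("all haplotypes in the table must have equal length")

    rng = np.random.default_rng(seed)
    if mode == "sample":
        counts = rng.multinomial(n_haplotypes, p)
    elif mode == "exact":
        raw = p * n_haplotypes
        counts = np.floor(raw).astype(np.int64)
        remainder = raw - counts
        short = n_haplotypes - counts.sum()
        # largest remainders get the leftover copies; ties by table order
        for i in np.argsort(-remainder, kind="stable")[:short]:
            counts[i] += 1
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    alleles = np.repeat(np.array(haps, dtype=np.uint8), counts, axis=0)
    perm = rng.permutation(alleles.shape[0])
    alleles = alleles[perm]

    freq = alleles.mean(axis=0)
    if np.any((freq <= 0) | (freq >= 1)):
        bad = np.flatnonzero((freq <= 0) | (freq >= 1))
        raise ValueError(
            f"monomorphic site(s) at column(s) {bad.tolist()}: every site must be "
            "polymorphic in the realized panel"
        )
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    if site_ids is None:
        site_ids = np.array([f"snp{p}" for p in positions], dtype=object)
    return HaplotypePanel(alleles, positions, site_ids)


def pair_into_diploids(
    panel: HaplotypePanel, n_samples: int, seed: int = 0
) -> GenotypeDataset:
    """Randomly pair panel haplotypes (sampling with replacement) into diploids.

    Dosage at each site is the sum of the two sampled haplotype alleles, so
    all dosages are hard {0, 1, 2} calls; every site is flagged genotyped
    with info score 1.  The sampled haplotypes are retained on the dataset
    so the imputation emulator can operate per true haplotype.
    """
    if panel.n_haplotypes < 2:
        raise ValueError("panel must contain at least 2 haplotypes")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, panel.n_haplotypes, size=2 * n_samples)
    haps = panel.alleles[idx]
    dosages = haps[0::2].astype(np.float64) + haps[1::2].astype(np.float64)
    # interleave back to (2N, M) with sample i's haplotypes at rows 2i, 2i+1
    p = dosages.mean(axis=0) / 2.0
    sites = pd.DataFrame(
        {
            "id": panel.site_ids,
            "position": panel.positions,
            "maf": np.minimum(p, 1 - p),
            "genotyped": True,
            "info": 1.0,
            "hwe_p": np.nan,
            "missing_rate": 0.0,
        },
        columns=SITE_COLUMNS,
    )
    sample_ids = np.array([f"s{i}" for i in range(n_samples)], dtype=object)
    return GenotypeDataset(dosages, sample_ids, sites, haplotypes=haps)
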