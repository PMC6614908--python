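"""Additive-model phenotype simulation with known causal variants.

Phenotypes emulate DNA methylation at a CpG-SNP after covariate correction:
a Gaussian trait y = sum_c X_c beta_c + e, with per-causal effects drawn
from N(0, 1) and the environmental variance set so the genetic fraction of
the phenotypic variance equals the target narrow-sense heritability.  With
a single causal variant the heritability IS the variance explained by that
variant, which is what makes the trait a clean fine-mapping benchmark.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypeDataset, PhenotypeVector
from .haplosim import build_panel_from_haplotype_table, pair_into_diploids

__all__ = ["simulate_phenotype", "build_masking_scenario"]


def simulate_phenotype(
    truth: GenotypeDataset,
    causal_ids: list[str],
    h2_target: float,
    seed: int = 0,
    causal_maf_min: float = 0.05,
    betas: np.ndarray | None = None,
) -> PhenotypeVector:
    """Simulate y = X_c beta + e at a target heritability.

    Effects are N(0, 1) draws (or supplied via ``betas``); the noise s.d.
    is chosen so that the genetic variance — computed from the realized
    covariance of the causal dosages, which handles causal sites in LD —
    is the fraction ``h2_target`` of the total phenotypic variance at the
    population level.  ``h2_target = 0`` returns pure N(0, 1) noise.
    """
    if not 0.0 <= h2_target < 1.0:
        raise ValueError("h2_target must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = truth.n_samples

    if h2_target == 0.0:
        return PhenotypeVector(
            values=rng.standard_normal(n),
            causal_ids=list(causal_ids),
            true_betas=np.zeros(len(causal_ids)),
            h2_target=0.0,
            seed=seed,
        )
    if not causal_ids:
        raise ValueError("h2_target > 0 requires at least one causal site")

    idx = [truth.site_index(s) for s in causal_ids]
    mafs = truth.recompute_maf().sites["maf"].to_numpy()[idx]
    low = [s for s, m in zip(causal_ids, mafs) if m < causal_maf_min]
    if low:
        raise ValueError(
            f"causal site(s) below the MAF floor {causal_maf_min}: {low}"
        )

    Xc = truth.dosages[:, idx]
    if betas is None:
        betas = rng.standard_normal(len(causal_ids))
    else:
        betas = np.asarray(betas, dtype=np.float64)
    g = Xc @ betas
    var_g = float(np.var(g))
    if var_g <= 0:
        raise ValueError("causal sites contribute zero genetic variance")
    sigma_e = np.sqrt(var_g * (1.0 - h2_target) / h2_target)
    y = g + rng.normal(0.0, sigma_e, size=n)
    return PhenotypeVector(
        values=y,
        causal_ids=list(causal_ids),
        true_betas=betas,
        h2_target=h2_target,
        seed=seed,
    )


def build_masking_scenario(
    n_samples: int = 1366,
    maf_cpg: float = 0.15,
    maf_top: float = 0.30,
    effect_cpg: float = -0.5,
    effect_top: float = -1.0,
    h2_target: float = 0.2,
    seed: int = 0,
    n_neutral: int = 10,
) -> tuple[GenotypeDataset, PhenotypeVector]:
    """Construct the masking locus: a top SNP whose minor allele carries
    every CpG-SNP minor allele (D' = 1, r2 < 1) plus extra trait-lowering
    chromosomes.

    The two-locus haplotype table omits the {top-major, cpg-minor} class:

    ========  =========  ==================
    top SNP   CpG-SNP    frequency
    ========  =========  ==================
    minor     minor      maf_cpg
    minor     major      maf_top - maf_cpg
    major     major      1 - maf_top
    ========  =========  ==================

    Both minor alleles lower the trait (effects must share a sign); since
    the top SNP's minor allele is strictly more frequent and absorbs the
    whole CpG signal, the top SNP explains more phenotypic variance than
    the causal CpG-SNP — single-SNP ranking and credible sets latch onto
    the top SNP while conditional analysis sees only one signal.
    ``n_neutral`` unlinked polymorphic sites pad the locus so credible-set
    construction has non-trivial candidates.
    """
    if maf_top <= maf_cpg:
        raise ValueError("maf_top must exceed maf_cpg for masking to be possible")
    if effect_cpg * effect_top < 0:
        raise ValueError("masking requires effects of the same sign")
    rng = np.random.default_rng(seed)

    # columns: (top, cpg); minor allele coded 1
    table = {
        (1, 1): maf_cpg,
        (1, 0): maf_top - maf_cpg,
        (0, 0): 1.0 - maf_top,
    }
    core_positions = np.array([50_000, 51_000])
    core_ids = np.array(["top_snp", "cpg_snp"], dtype=object)
    panel = build_panel_from_haplotype_table(
        table,
        n_haplotypes=2 * n_samples,
        seed=int(rng.integers(2**31 - 1)),
        mode="sample",
        positions=core_positions,
        site_ids=core_ids,
    )

    data = pair_into_diploids(panel, n_samples, seed=int(rng.integers(2**31 - 1)))

    if n_neutral > 0:
        neutral_maf = rng.uniform(0.05, 0.5, size=n_neutral)
        neutral_haps = (
            rng.random((2 * n_samples, n_neutral)) < neutral_maf[None, :]
        ).astype(np.uint8)
        dosages = np.column_stack(
            [data.dosages, neutral_haps[0::2] + neutral_haps[1::2]]
        )
        haplotypes = np.column_stack([data.haplotypes, neutral_haps])
        positions = np.concatenate(
            [core_positions, 52_000 + 1_000 * np.arange(1, n_neutral + 1)]
        )
        ids = np.concatenate(
            [core_ids, np.array([f"neutral{i}" for i in range(n_neutral)], dtype=object)]
        )
        p = dosages.mean(axis=0) / 2.0
        sites = pd.DataFrame(
            {
                "id": ids,
                "position": positions,
                "maf": np.minimum(p, 1 - p),
                "genotyped": True,
                "info": 1.0,
                "hwe_p": np.nan,
                "missing_rate": 0.0,
            }
        )
        data = GenotypeDataset(
            dosages, data.sample_ids, sites, haplotypes=haplotypes
        )

    pheno = simulate_phenotype(
        data,
        causal_ids=["cpg_snp", "top_snp"],
        h2_target=h2_target,
        seed=int(rng.integers(2**31 - 1)),
        causal_maf_min=0.0,
        betas=np.array([effect_cpg, effect_top]),
    )
    return data, pheno
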