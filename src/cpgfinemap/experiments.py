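"""Pre-registered simulation experiments.

Each function runs one of the package's headline Monte-Carlo experiments
at its frozen study conditions and returns the summary quantities.  The
conditions (sample sizes, heritability, panel sizes, locus counts) are
part of the experimental design, not tuning knobs; docs/methods.md
records why each value was chosen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assoc, credsets, evalreport, multisignal, phenosim
from .haplosim import ScenarioConfig, build_panel_mosaic, pair_into_diploids
from .pipeline import ArmConfig, ExperimentConfig, run_experiment

__all__ = [
    "nominal_coverage",
    "heritability_recovery",
    "degradation_ordering",
    "masking_reproduction",
    "stratified_coverage",
]


def nominal_coverage(
    seed: int, n_loci: int = 300, n_samples: int = 1366, h2: float = 0.2
) -> pd.DataFrame:
    """Coverage of the causal SNP on true genotypes, per method.

    300 single-causal loci (mosaic panels, ~100-200 polymorphic sites,
    causal MAF > 0.05), phenotypes at h2 = 0.2, n = 1366; all three
    credible-set constructors run on the true genotypes.  Under a correct
    single-causal model each method's 95% set should contain the causal
    site at >= 95% of loci up to binomial error.
    """
    config = ExperimentConfig(
        n_loci=n_loci,
        n_samples=n_samples,
        n_sites=150,
        h2=h2,
        causal_maf_min=0.05,
        arms=[ArmConfig("truth")],
        master_seed=seed,
    )
    report, _ = run_experiment(config)
    return report


def heritability_recovery(
    seed: int,
    n_replicates: int = 500,
    n_samples: int = 1366,
    h2: float = 0.2,
) -> dict:
    """Mean realized variance explained by the causal SNP over replicates.

    One fixed genotype dataset; per replicate, a fresh phenotype at the
    target heritability and the regression r^2 of phenotype on the causal
    dosage.  The mean across replicates estimates the realized
    heritability and should match the generating value within Monte-Carlo
    error.
    """
    rng = np.random.default_rng(seed)
    scen = ScenarioConfig(
        n_samples=n_samples, n_sites=120, causal_maf_min=0.05, seed=int(rng.integers(2**31 - 1))
    )
    panel = build_panel_mosaic(scen)
    data = pair_into_diploids(panel, n_samples, seed=int(rng.integers(2**31 - 1)))
    maf = data.sites["maf"].to_numpy()
    causal_idx = int(rng.choice(np.flatnonzero(maf > 0.05)))
    causal_id = str(data.site_ids[causal_idx])

    r2s = np.empty(n_replicates)
    for r in range(n_replicates):
        pheno = phenosim.simulate_phenotype(
            data, [causal_id], h2, seed=int(rng.integers(2**31 - 1))
        )
        *_, r2, _ = assoc.ols_single(data.dosages[:, causal_idx], pheno.values)
        r2s[r] = r2
    return {
        "mean_r2": float(r2s.mean()),
        "mc_se": float(r2s.std(ddof=1) / np.sqrt(n_replicates)),
        "h2_target": h2,
        "n_replicates": n_replicates,
    }


def degradation_ordering(seed: int, n_loci: int = 300) -> pd.DataFrame:
    """Coverage per method across truth / large-panel / small-panel arms.

    Matched seeds across arms.  Both reference panels are external to the
    study population (as real panels are), differing on the two axes that
    set imputation quality: the large panel has 8x the haplotypes and 2%
    divergence, the small one 5% — the contrast between a large
    well-matched reference and a small cosmopolitan one.
    QC uses the permissive info >= 0.3 threshold so poorly imputed causal
    variants remain in the analysis (the regime in which imputation error
    degrades fine-mapping, rather than simply deleting the variant); arms
    are restricted to their common post-QC sites, and a causal variant
    absent from that intersection counts as a miss in every arm.
    """
    from .imputesim import QCConfig

    config = ExperimentConfig(
        n_loci=n_loci,
        n_samples=1366,
        n_sites=100,
        h2=0.2,
        causal_maf_min=0.05,
        array_stride=4,
        causal_on_array=False,
        arms=[
            ArmConfig("truth"),
            ArmConfig("imputed_large", ref_haplotypes=400, drift=0.02),
            ArmConfig("imputed_small", ref_haplotypes=50, drift=0.05),
        ],
        qc_config=QCConfig(info_min=0.3),
        master_seed=seed,
    )
    report, _ = run_experiment(config)
    return report


def masking_reproduction(seed: int, n_seeds: int = 50) -> dict:
    """How often the masking locus hides its causal CpG-SNP.

    For each replicate of the masking scenario (D' = 1 top SNP at higher
    MAF, both alleles trait-lowering) we record whether each method's
    credible set excludes the CpG-SNP and whether each conditional method
    reports exactly one signal.
    """
    excluded = {"jtest": 0, "ppa": 0, "mcmc_count": 0}
    single_signal = {"forward": 0, "stepwise": 0}
    top_is_signal = 0
    rng = np.random.default_rng(seed)
    for _ in range(n_seeds):
        s = int(rng.integers(2**31 - 1))
        data, pheno = phenosim.build_masking_scenario(seed=s)
        cs_j = credsets.jtest_credible_set(data, pheno)
        bfs = credsets.compute_bayes_factors(data, pheno)
        cs_p = credsets.ppa_credible_set(bfs)
        cs_m = credsets.mcmc_credible_set(data, pheno, seed=s)
        for name, cs in (("jtest", cs_j), ("ppa", cs_p), ("mcmc_count", cs_m)):
            if "cpg_snp" not in cs.members:
                excluded[name] += 1
        fwd = multisignal.forward_selection(data, pheno)
        stw = multisignal.stepwise_joint_selection(data, pheno)
        if fwd.n_signals == 1:
            single_signal["forward"] += 1
        if stw.n_signals == 1:
            single_signal["stepwise"] += 1
        if fwd.signals and fwd.signals[0] == "top_snp":
            top_is_signal += 1
    return {
        "n_seeds": n_seeds,
        "excluded_fraction": {k: v / n_seeds for k, v in excluded.items()},
        "single_signal_fraction": {k: v / n_seeds for k, v in single_signal.items()},
        "top_snp_is_signal_fraction": top_is_signal / n_seeds,
    }


def stratified_coverage(seed: int, n_loci_per_stratum: int = 75) -> pd.DataFrame:
    """Coverage with the causal site genotyped on the array vs imputed.

    Two matched sub-experiments against the same small reference panel,
    differing only in whether the causal site is on the emulated array;
    dosage error at the causal site is what separates the strata.
    Returns the two-row stratified report per method.
    """
    reports = []
    records_all = []
    for on_array, sub_seed in ((True, seed), (False, seed + 1)):
        config = ExperimentConfig(
            n_loci=n_loci_per_stratum,
            n_samples=500,
            n_sites=100,
            h2=0.2,
            causal_maf_min=0.05,
            array_stride=4,
            causal_on_array=on_array,
            arms=[ArmConfig("imputed", ref_haplotypes=50, drift=0.01)],
            master_seed=sub_seed,
        )
        _, records = run_experiment(config)
        records_all.extend(records)

    rows = []
    for method in ("jtest", "ppa", "mcmc_count"):
        sets = [r["arms"]["imputed"]["sets"][method] for r in records_all]
        causals = [r["causal_id"] for r in records_all]
        flags = [r["causal_genotyped"] for r in records_all]
        strat = evalreport.stratify_by_provenance(sets, causals, flags)
        strat["method"] = method
        rows.append(strat)
    return pd.concat(rows)
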