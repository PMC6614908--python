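"""End-to-end experiment orchestration and file interchange.

``run_experiment`` drives the full design: simulate a truth population and
phenotype per locus, derive dataset arms (true genotypes, and array-masked
genotypes imputed against reference panels of differing size/divergence),
QC and intersect the arms, run the credible-set methods and conditional
analyses, and aggregate coverage per (method, arm).  Everything is a pure
function of the configuration and the master seed: per-locus child seeds
are spawned deterministically, so any single locus can be reproduced in
isolation.

VCF is the sole genotype interchange format (GT for hard calls, DS for
dosages, site-level info score and genotyped flag in INFO).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import credsets, evalreport, imputesim, multisignal, phenosim
from .core import CredibleSet, GenotypeDataset, HaplotypePanel, PhenotypeVector, SITE_COLUMNS
from .haplosim import ScenarioConfig, build_panel_mosaic, pair_into_diploids
from .imputesim import QCConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ArmConfig",
    "ExperimentConfig",
    "run_experiment",
    "run_locus",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "write_phenotype_tsv",
    "read_phenotype_tsv",
    "write_truth_json",
]


@dataclass
class ArmConfig:
    """One dataset arm: the truth genotypes or an imputation emulation.

    ``ref_haplotypes = 0`` means the arm uses the true genotypes directly.
    ``drift`` adds private allele flips to the reference haplotypes at the
    given per-site rate, emulating a reference panel drawn from a related
    but diverged population (a small cosmopolitan panel vs a large matched
    one).  ``qc`` applies post-imputation variant QC to the arm.
    """

    name: str
    ref_haplotypes: int = 0
    drift: float = 0.0
    qc: bool = True
    mismatch_rate: float = 0.005
    switch_rate: float = 1e-6


@dataclass
class ExperimentConfig:
    """Full experiment design: scenario x arms x methods x loci."""

    n_loci: int = 300
    n_samples: int = 1366
    n_sites: int = 120
    h2: float = 0.2
    causal_maf_min: float = 0.05
    n_founders: int = 12
    recomb_rate: float = 2e-6
    mutation_rate: float = 0.002
    region_length: int = 200_000
    array_stride: int = 4
    causal_on_array: bool = False
    arms: list[ArmConfig] = field(default_factory=lambda: [ArmConfig("truth")])
    methods: tuple[str, ...] = ("jtest", "ppa", "mcmc_count")
    level: float = 0.95
    qc_config: QCConfig = field(default_factory=QCConfig)
    run_conditional: bool = False
    master_seed: int = 0

    def __post_init__(self) -> None:
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise ValueError("arm names must be unique")
        for f in ("n_loci", "n_samples", "n_sites", "array_stride", "master_seed"):
            if not isinstance(getattr(self, f), (int, np.integer)):
                raise ValueError(f"{f} must be an integer")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        payload = json.loads(Path(path).read_text())
        arms = [ArmConfig(**a) for a in payload.pop("arms", [{"name": "truth"}])]
        qc = QCConfig(**payload.pop("qc_config", {}))
        payload.pop("methods_tuple", None)
        methods = tuple(payload.pop("methods", ("jtest", "ppa", "mcmc_count")))
        return cls(arms=arms, qc_config=qc, methods=methods, **payload)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["methods"] = list(self.methods)
        Path(path).write_text(json.dumps(payload, indent=2))


def _child_seeds(master_seed: int, locus: int, n: int) -> list[int]:
    ss = np.random.SeedSequence([int(master_seed), int(locus)])
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def _build_credible_set(
    method: str, data: GenotypeDataset, y: PhenotypeVector, level: float, seed: int
) -> CredibleSet:
    if method == "jtest":
        return credsets.jtest_credible_set(data, y, alpha=1.0 - level)
    if method == "ppa":
        bfs = credsets.compute_bayes_factors(data, y)
        return credsets.ppa_credible_set(bfs, level=level)
    if method == "mcmc_count":
        return credsets.mcmc_credible_set(data, y, level=level, seed=seed)
    raise ValueError(f"unknown method: {method!r}")


def run_locus(config: ExperimentConfig, locus: int) -> dict:
    """Simulate and fine-map one locus; returns the per-locus record.

    The record holds, per arm: the credible set per method, whether the
    causal site survived to analysis, and whether it was genotyped on the
    emulated array; plus optional conditional-analysis results.
    """
    seeds = _child_seeds(config.master_seed, locus, 8)
    n_ref = sum(a.ref_haplotypes for a in config.arms)
    scen = ScenarioConfig(
        n_samples=config.n_samples,
        n_sites=config.n_sites,
        causal_maf_min=config.causal_maf_min,
        n_founders=config.n_founders,
        recomb_rate=config.recomb_rate,
        mutation_rate=config.mutation_rate,
        region_length=config.region_length,
        n_haplotypes=2 * config.n_samples + n_ref,
        seed=seeds[0],
    )
    panel = build_panel_mosaic(scen)
    rng = np.random.default_rng(seeds[1])

    study_panel = HaplotypePanel(
        panel.alleles[: 2 * config.n_samples], panel.positions, panel.site_ids
    )
    truth = pair_into_diploids(study_panel, config.n_samples, seed=seeds[2])

    maf = truth.sites["maf"].to_numpy()
    eligible = np.flatnonzero(maf > config.causal_maf_min)
    if len(eligible) == 0:
        raise RuntimeError("no site clears the causal MAF floor")
    causal_idx = int(rng.choice(eligible))
    causal_id = str(truth.site_ids[causal_idx])

    pheno = phenosim.simulate_phenotype(
        truth, [causal_id], config.h2, seed=seeds[3], causal_maf_min=config.causal_maf_min
    )

    # array = every stride-th site; causal membership per design flag
    array_mask = np.zeros(truth.n_sites, dtype=bool)
    array_mask[:: config.array_stride] = True
    array_mask[causal_idx] = config.causal_on_array
    if array_mask.sum() < 2:
        raise RuntimeError("array site set too small")
    array_ids = truth.site_ids[array_mask]

    # derive arms
    arm_data: dict[str, GenotypeDataset] = {}
    offset = 2 * config.n_samples
    for arm in config.arms:
        if arm.ref_haplotypes == 0:
            arm_data[arm.name] = truth
            continue
        ref_rows = panel.alleles[offset : offset + arm.ref_haplotypes]
        offset += arm.ref_haplotypes
        if arm.drift > 0:
            flips = np.random.default_rng(seeds[4]).random(ref_rows.shape) < arm.drift
            ref_rows = np.where(flips, 1 - ref_rows, ref_rows).astype(np.uint8)
        ref_panel = HaplotypePanel(ref_rows, panel.positions, panel.site_ids)
        masked = imputesim.mask_to_array(truth, array_ids)
        imputed = imputesim.impute_li_stephens(
            masked, ref_panel, mismatch_rate=arm.mismatch_rate, switch_rate=arm.switch_rate
        )
        if arm.qc:
            imputed, _ = imputesim.apply_qc(imputed, config.qc_config)
        arm_data[arm.name] = imputed

    if len(arm_data) > 1:
        names = list(arm_data)
        restricted = imputesim.intersect_datasets(*[arm_data[n] for n in names])
        arm_data = dict(zip(names, restricted))

    record: dict = {
        "locus": locus,
        "causal_id": causal_id,
        "causal_genotyped": bool(array_mask[causal_idx]),
        "arms": {},
    }
    for k, (name, data) in enumerate(arm_data.items()):
        analyzed = set(data.site_ids)
        sets = {
            method: _build_credible_set(
                method, data, pheno, config.level, seed=seeds[5] + k
            )
            for method in config.methods
        }
        record["arms"][name] = {
            "sets": sets,
            "causal_analyzed": causal_id in analyzed,
            "analyzed_ids": analyzed,
        }
        if config.run_conditional:
            record["arms"][name]["forward"] = multisignal.forward_selection(data, pheno)
            record["arms"][name]["stepwise"] = multisignal.stepwise_joint_selection(
                data, pheno
            )
    return record


def run_experiment(config: ExperimentConfig, out_dir=None) -> tuple[pd.DataFrame, list[dict]]:
    """Run all loci and aggregate coverage per (method, arm).

    Loci that fail any stage are quarantined with a logged reason; the run
    errors out only if more than half the loci are quarantined.  Returns
    the Table-1-shaped report and the per-locus records.
    """
    records: list[dict] = []
    quarantined = 0
    for locus in range(config.n_loci):
        try:
            records.append(run_locus(config, locus))
        except Exception as exc:  # noqa: BLE001 - quarantine any stage failure
            quarantined += 1
            logger.warning("locus %d quarantined: %s", locus, exc)
    if quarantined > config.n_loci / 2:
        raise RuntimeError(
            f"{quarantined}/{config.n_loci} loci quarantined; run aborted"
        )

    rows = []
    for arm in config.arms:
        for method in config.methods:
            sets = [r["arms"][arm.name]["sets"][method] for r in records]
            causals = [r["causal_id"] for r in records]
            analyzed = [r["arms"][arm.name]["analyzed_ids"] for r in records]
            row = evalreport.coverage(sets, causals, analyzed)
            row["method"] = method
            row["arm"] = arm.name
            rows.append(row)
    report = pd.DataFrame(rows)[
        ["method", "arm", "coverage", "n_loci", "mean_set_size", "median_set_size", "q95_set_size"]
    ].reset_index(drop=True)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "coverage_report.tsv", sep="\t", index=False)
        per_set = []
        for r in records:
            for arm_name, arm_rec in r["arms"].items():
                for method, cs in arm_rec["sets"].items():
                    per_set.append(
                        {
                            "locus": r["locus"],
                            "arm": arm_name,
                            "method": method,
                            "set_size": cs.size,
                            "contains_causal": cs.contains_causal,
                            "members": ",".join(cs.members),
                        }
                    )
        pd.DataFrame(per_set).to_csv(out_dir / "credible_sets.tsv", sep="\t", index=False)
    return report, records


# ---------------------------------------------------------------------------
# file interchange


def write_genotypes_vcf(data: GenotypeDataset, path, chrom: str = "1") -> None:
    """Write a dataset as an uncompressed VCF (GT + DS; INFO score, flag).

    When the dataset carries its true haplotypes the GT field is written
    phased (``a|b``), so a read-back recovers them; otherwise GT is the
    unphased hard call implied by the rounded dosage.
    """
    header = pysam.VariantHeader()
    header.add_line(
        f"##contig=<ID={chrom},length={int(data.sites['position'].max()) + 1000}>"
    )
    header.add_line(
        '##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">'
    )
    header.add_line('##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Genotyped site">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Posterior mean dosage">'
    )
    for s in data.sample_ids:
        header.add_sample(str(s))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for m in range(data.n_sites):
            rec = vcf.new_record(
                contig=chrom,
                start=int(data.sites["position"].iloc[m]) - 1,
                stop=int(data.sites["position"].iloc[m]),
                alleles=("A", "G"),
                id=str(data.sites["id"].iloc[m]),
            )
            info = data.sites["info"].iloc[m]
            if np.isfinite(info):
                rec.info["INFO"] = float(np.round(info, 4))
            if bool(data.sites["genotyped"].iloc[m]):
                rec.info["TYPED"] = True
            for i, s in enumerate(data.sample_ids):
                d = float(data.dosages[i, m])
                if data.haplotypes is not None:
                    h1 = int(data.haplotypes[2 * i, m])
                    h2 = int(data.haplotypes[2 * i + 1, m])
                    rec.samples[str(s)]["GT"] = (h1, h2)
                    rec.samples[str(s)].phased = True
                else:
                    g = int(np.rint(d))
                    rec.samples[str(s)]["GT"] = [(0, 0), (0, 1), (1, 1)][g]
                rec.samples[str(s)]["DS"] = float(np.round(d, 3))
            vcf.write(rec)


def read_genotypes_vcf(path) -> GenotypeDataset:
    """Read a biallelic VCF into a dataset; DS takes precedence over GT."""
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        has_info = "INFO" in vcf.header.info
        has_typed = "TYPED" in vcf.header.info
        dosages_cols, hap_cols, ids, positions, infos, typed = [], [], [], [], [], []
        all_phased = True
        for k, rec in enumerate(vcf.fetch(), start=1):
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"record {k} at {rec.chrom}:{rec.pos} is not biallelic"
                )
            col = np.empty(len(samples))
            hcol = np.zeros(2 * len(samples), dtype=np.uint8)
            for i, s in enumerate(samples):
                fmt = rec.samples[s]
                gt = fmt.get("GT")
                if gt is not None and not any(a is None for a in gt) and fmt.phased:
                    hcol[2 * i], hcol[2 * i + 1] = int(gt[0]), int(gt[1])
                else:
                    all_phased = False
                ds = fmt.get("DS")
                if ds is not None:
                    col[i] = float(ds)
                elif gt is not None and not any(a is None for a in gt):
                    col[i] = float(sum(gt))
                else:
                    raise ValueError(f"record {k}: sample {s} has no GT/DS")
            dosages_cols.append(col)
            hap_cols.append(hcol)
            ids.append(rec.id or f"snp{rec.pos}")
            positions.append(rec.pos)
            infos.append(float(rec.info.get("INFO", 1.0)) if has_info else 1.0)
            typed.append(bool(rec.info.get("TYPED", False)) if has_typed else False)
    if not dosages_cols:
        raise ValueError("VCF contains no records")
    dosages = np.column_stack(dosages_cols)
    haplotypes = np.column_stack(hap_cols) if all_phased else None
    p = dosages.mean(axis=0) / 2.0
    sites = pd.DataFrame(
        {
            "id": np.array(ids, dtype=object),
            "position": positions,
            "maf": np.minimum(p, 1 - p),
            "genotyped": typed,
            "info": infos,
            "hwe_p": np.nan,
            "missing_rate": 0.0,
        },
        columns=SITE_COLUMNS,
    )
    return GenotypeDataset(
        dosages, np.array(samples, dtype=object), sites, haplotypes=haplotypes
    )


def write_phenotype_tsv(pheno: PhenotypeVector, sample_ids, path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "value": pheno.values}).to_csv(
        path, sep="\t", index=False
    )


def read_phenotype_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_json(pheno: PhenotypeVector, path) -> None:
    """Hidden-truth sidecar, kept separate from the phenotype table."""
    Path(path).write_text(
        json.dumps(
            {
                "causal_ids": pheno.causal_ids,
                "true_betas": pheno.true_betas.tolist(),
                "h2_target": pheno.h2_target,
                "seed": pheno.seed,
            },
            indent=2,
        )
    )
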