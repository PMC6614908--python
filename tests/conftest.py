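import logging

import numpy as np
import pandas as pd
import pytest

from cpgfinemap.core import GenotypeDataset, HaplotypePanel, SITE_COLUMNS
from cpgfinemap.haplosim import ScenarioConfig, build_panel_mosaic, pair_into_diploids
from cpgfinemap.phenosim import simulate_phenotype

logging.getLogger("cpgfinemap").setLevel(logging.ERROR)


def make_dataset(dosages, positions=None, ids=None, haplotypes=None) -> GenotypeDataset:
    """Assemble a GenotypeDataset from a raw dosage matrix."""
    dosages = np.asarray(dosages, dtype=np.float64)
    n, m = dosages.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if ids is None:
        ids = np.array([f"s{p}" for p in positions], dtype=object)
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
        },
        columns=SITE_COLUMNS,
    )
    samples = np.array([f"i{i}" for i in range(n)], dtype=object)
    return GenotypeDataset(dosages, samples, sites, haplotypes=haplotypes)


@pytest.fixture(scope="session")
def locus():
    """A medium simulated locus with a strong single causal variant."""
    scen = ScenarioConfig(n_samples=400, n_sites=80, seed=42)
    panel = build_panel_mosaic(scen)
    data = pair_into_diploids(panel, 400, seed=43)
    eligible = np.flatnonzero(data.sites["maf"].to_numpy() > 0.05)
    causal_id = str(data.site_ids[eligible[len(eligible) // 2]])
    pheno = simulate_phenotype(data, [causal_id], 0.3, seed=44)
    return data, pheno, causal_id


@pytest.fixture(scope="session")
def small_panel():
    scen = ScenarioConfig(n_samples=100, n_sites=40, seed=7)
    return build_panel_mosaic(scen)
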