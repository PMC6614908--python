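import math

import numpy as np
import pytest

from cpgfinemap.core import HaplotypePanel
from cpgfinemap.haplosim import ScenarioConfig, build_panel_mosaic, pair_into_diploids
from cpgfinemap.imputesim import (
    QCConfig,
    apply_qc,
    hwe_exact_p,
    impute_li_stephens,
    info_score,
    intersect_datasets,
    mask_to_array,
)

from conftest import make_dataset


class TestMaskToArray:
    def test_identity_when_all_sites_on_array(self, locus):
        data, _, _ = locus
        out = mask_to_array(data, list(data.site_ids))
        assert np.array_equal(out.dosages, data.dosages)

    def test_empty_array_set_rejected(self, locus):
        data, _, _ = locus
        with pytest.raises(ValueError, match="empty"):
            mask_to_array(data, [])

    def test_cardinality_and_unknown_ids(self, locus):
        data, _, _ = locus
        keep = list(data.site_ids[:20])
        out = mask_to_array(data, keep)
        assert out.n_sites == 20
        assert out.sites["genotyped"].all()
        with pytest.raises(KeyError, match="nope"):
            mask_to_array(data, keep + ["nope"])


class TestLiStephens:
    def test_perfect_panel_limit(self):
        """Targets verbatim in the reference, tiny mismatch -> exact recovery.

        The haplotype pool is a handful of distinct founders (no
        recombination/mutation) so the array sites identify each target's
        template uniquely and the posterior collapses onto it.
        """
        panel = build_panel_mosaic(
            ScenarioConfig(
                n_samples=60, n_sites=50, n_founders=6,
                recomb_rate=0.0, mutation_rate=0.0, seed=21,
            )
        )
        data = pair_into_diploids(panel, 60, seed=22)
        # reference = exactly the haplotypes the targets carry
        ref = HaplotypePanel(data.haplotypes, panel.positions, panel.site_ids)
        masked = mask_to_array(data, list(data.site_ids[::4]))
        imp = impute_li_stephens(masked, ref, mismatch_rate=1e-6, switch_rate=1e-8)
        assert np.max(np.abs(imp.dosages - data.dosages)) < 0.05

    def test_uniform_reference_copies_reference(self):
        hap = np.array([1, 0, 1, 0, 1], dtype=np.uint8)
        ref = HaplotypePanel(
            np.tile(hap, (4, 1)), np.arange(1, 6) * 10, [f"v{i}" for i in range(5)]
        )
        targets = np.array([[0, 1, 0, 0, 1], [1, 1, 1, 0, 0]], dtype=np.uint8)
        arr = targets[:, [0, 2]]
        data = make_dataset(
            (arr[0] + arr[1]).astype(float)[None, :],
            positions=[10, 30],
            ids=["v0", "v2"],
            haplotypes=arr,
        )
        imp = impute_li_stephens(data, ref, mismatch_rate=0.1)
        unobserved = [1, 3, 4]
        assert np.allclose(imp.dosages[:, unobserved], 2 * hap[unobserved], atol=1e-6)

    def test_accuracy_improves_with_reference_size(self):
        """Mean dosage error strictly decreases over 50 -> 500 -> 5000 haplotypes."""
        sizes = (50, 500, 5000)
        errs = {s: [] for s in sizes}
        for seed in range(6):
            scen = ScenarioConfig(
                n_samples=100,
                n_sites=60,
                n_haplotypes=200 + max(sizes),
                seed=500 + seed,
            )
            panel = build_panel_mosaic(scen)
            study = HaplotypePanel(panel.alleles[:200], panel.positions, panel.site_ids)
            data = pair_into_diploids(study, 100, seed=600 + seed)
            masked = mask_to_array(data, list(data.site_ids[::5]))
            for s in sizes:
                ref = HaplotypePanel(
                    panel.alleles[200 : 200 + s], panel.positions, panel.site_ids
                )
                imp = impute_li_stephens(masked, ref)
                errs[s].append(np.abs(imp.dosages - data.dosages).mean())
        means = [np.mean(errs[s]) for s in sizes]
        assert means[0] > means[1] > means[2]

    def test_deterministic(self, locus):
        data, _, _ = locus
        ref = HaplotypePanel(
            data.haplotypes[:100],
            data.sites["position"].to_numpy(),
            data.site_ids,
        )
        masked = mask_to_array(data, list(data.site_ids[::3]))
        a = impute_li_stephens(masked, ref)
        b = impute_li_stephens(masked, ref)
        assert np.array_equal(a.dosages, b.dosages)

    def test_site_mismatch_rejected(self, locus):
        data, _, _ = locus
        ref = HaplotypePanel(
            data.haplotypes[:50, :10],
            data.sites["position"].to_numpy()[:10],
            data.site_ids[:10],
        )
        masked = mask_to_array(data, list(data.site_ids[::3]))
        with pytest.raises(KeyError):
            impute_li_stephens(masked, ref)


class TestInfoScore:
    def test_hand_computed_value(self):
        # var({0,1,1,2}) = 0.5 (population), 2p(1-p) = 0.5 at p = 0.5
        assert info_score(np.array([0.0, 1.0, 1.0, 2.0]), 0.5) == pytest.approx(1.0)

    def test_hard_hwe_dosages_score_near_one(self):
        rng = np.random.default_rng(1)
        p = 0.3
        d = rng.binomial(2, p, size=20000).astype(float)
        assert info_score(d, d.mean() / 2) == pytest.approx(1.0, abs=0.02)

    def test_pure_prior_scores_zero(self):
        assert info_score(np.full(100, 0.6), 0.3) == 0.0

    def test_monomorphic_is_nan(self):
        assert math.isnan(info_score(np.zeros(10), 0.0))


class TestHWEExact:
    @pytest.mark.parametrize(
        "n_het,n_hom1,n_hom2",
        [(10, 5, 85), (50, 25, 25), (0, 10, 10), (20, 0, 80), (57, 14, 50)],
    )
    def test_matches_brute_force_enumeration(self, n_het, n_hom1, n_hom2):
        """Oracle: enumerate all het counts via exact binomial coefficients."""
        n = n_het + n_hom1 + n_hom2
        rare = 2 * min(n_hom1, n_hom2) + n_het

        def weight(h):
            rh = (rare - h) // 2
            return (
                math.factorial(n)
                // (math.factorial(h) * math.factorial(rh) * math.factorial(n - h - rh))
                * 2**h
            )

        hets = range(rare % 2, rare + 1, 2)
        total = sum(weight(h) for h in hets)
        cond = {h: weight(h) / total for h in hets}
        expected = sum(p for p in cond.values() if p <= cond[n_het] + 1e-12)
        assert hwe_exact_p(n_het, n_hom1, n_hom2) == pytest.approx(expected, rel=1e-9)

    def test_equilibrium_data_not_flagged(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.4, size=1000)
        p = hwe_exact_p(int((g == 1).sum()), int((g == 0).sum()), int((g == 2).sum()))
        assert p > 1e-4


class TestQC:
    def _toy(self):
        rng = np.random.default_rng(3)
        n = 1000
        cols, infos = [], []
        # 4 clean sites
        for p in (0.2, 0.3, 0.4, 0.25):
            cols.append(rng.binomial(2, p, n).astype(float))
            infos.append(1.0)
        # low MAF site
        cols.append(rng.binomial(2, 0.005, n).astype(float))
        infos.append(1.0)
        # low info site
        cols.append(rng.binomial(2, 0.3, n).astype(float))
        infos.append(0.79)
        data = make_dataset(np.column_stack(cols))
        sites = data.sites.copy()
        sites["info"] = infos
        sites["genotyped"] = [True] * 4 + [True, False]
        data.sites = sites
        return data

    def test_engineered_failures_removed(self):
        data = self._toy()
        out, log = apply_qc(data, QCConfig())
        assert out.n_sites == 4
        assert log.set_index("filter").loc["maf", "n_removed"] == 1
        assert log.set_index("filter").loc["info", "n_removed"] == 1

    def test_info_threshold_three_vs_eight(self):
        data = self._toy()
        strict, _ = apply_qc(data, QCConfig())
        lax, _ = apply_qc(data, QCConfig(info_min=0.3))
        assert strict.n_sites == 4 and lax.n_sites == 5

    def test_filters_commute(self):
        data = self._toy()
        combined, _ = apply_qc(data, QCConfig())
        step1, _ = apply_qc(data, QCConfig(maf_min=0.01, info_min=0.0, hwe_p_min=0.0))
        step2, _ = apply_qc(step1, QCConfig(maf_min=0.0, info_min=0.8, hwe_p_min=0.0))
        alt1, _ = apply_qc(data, QCConfig(maf_min=0.0, info_min=0.8, hwe_p_min=0.0))
        alt2, _ = apply_qc(alt1, QCConfig(maf_min=0.01, info_min=0.0, hwe_p_min=0.0))
        assert list(step2.site_ids) == list(combined.site_ids) == list(alt2.site_ids)

    def test_all_removed_raises(self):
        rng = np.random.default_rng(4)
        data = make_dataset(rng.binomial(2, 0.004, (2000, 3)).astype(float))
        with pytest.raises(ValueError, match="every site"):
            apply_qc(data, QCConfig())

    def test_hwe_violation_removed(self):
        rng = np.random.default_rng(5)
        ok = rng.binomial(2, 0.3, (800, 2)).astype(float)
        bad = rng.choice([0.0, 2.0], size=(800, 1))  # no hets at p ~ 0.5
        data = make_dataset(np.column_stack([ok, bad]))
        out, log = apply_qc(data, QCConfig())
        assert out.n_sites == 2
        assert log.set_index("filter").loc["hwe", "n_removed"] == 1


class TestIntersect:
    def test_identity(self, locus):
        data, _, _ = locus
        a, b = intersect_datasets(data, data)
        assert list(a.site_ids) == list(data.site_ids)

    def test_set_intersection(self):
        rng = np.random.default_rng(6)
        base = rng.binomial(2, 0.3, (50, 4)).astype(float)
        d1 = make_dataset(base[:, :3], ids=np.array(["A", "B", "C"], dtype=object))
        d2 = make_dataset(base[:, 1:], ids=np.array(["B", "C", "D"], dtype=object))
        a, b = intersect_datasets(d1, d2)
        assert list(a.site_ids) == ["B", "C"] == list(b.site_ids)

    def test_empty_intersection_raises(self):
        rng = np.random.default_rng(7)
        d1 = make_dataset(rng.binomial(2, 0.3, (30, 2)).astype(float), ids=np.array(["A", "B"], dtype=object))
        d2 = make_dataset(rng.binomial(2, 0.3, (30, 2)).astype(float), ids=np.array(["C", "D"], dtype=object))
        with pytest.raises(ValueError, match="no sites"):
            intersect_datasets(d1, d2)
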