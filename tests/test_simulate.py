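import numpy as np
import pandas as pd
import pytest

import feedeff as fe
from feedeff.simulate import SimulationError


class TestPedigreeGeneration:
    def test_minimal_trio(self):
        cfg = fe.SimConfig(n_founders=2, n_generations=1, offspring_per_mating=1, seed=0)
        ped, sex = fe.simulate_pedigree(cfg)
        assert len(ped) == 3
        assert ped.is_founder.sum() == 2
        child = int(np.where(~ped.is_founder)[0][0])
        assert ped.sire[child] >= 0 and ped.dam[child] >= 0

    def test_parent_closure(self):
        cfg = fe.SimConfig(n_founders=10, n_generations=3, offspring_per_mating=2, seed=1)
        ped, _ = fe.simulate_pedigree(cfg)
        for i in range(len(ped)):
            if not ped.is_founder[i]:
                assert 0 <= ped.sire[i] < i and 0 <= ped.dam[i] < i

    def test_birth_years_monotone_in_generation(self):
        cfg = fe.SimConfig(n_founders=8, n_generations=3, offspring_per_mating=2, seed=2)
        ped, _ = fe.simulate_pedigree(cfg)
        for i in range(len(ped)):
            for p in (ped.sire[i], ped.dam[i]):
                if p >= 0:
                    assert ped.birth_year[p] < ped.birth_year[i]

    def test_seed_determinism_and_sensitivity(self):
        a1, _ = fe.simulate_pedigree(fe.SimConfig(seed=1, n_founders=20))
        a2, _ = fe.simulate_pedigree(fe.SimConfig(seed=1, n_founders=20))
        b, _ = fe.simulate_pedigree(fe.SimConfig(seed=2, n_founders=20))
        assert a1.ids == a2.ids
        assert (a1.sire == a2.sire).all() and (a1.dam == a2.dam).all()
        assert not ((a1.sire == b.sire).all() and (a1.dam == b.dam).all())

    def test_invalid_counts_rejected(self):
        with pytest.raises(SimulationError):
            fe.SimConfig(n_founders=1)
        with pytest.raises(SimulationError):
            fe.SimConfig(weeks_per_cow=50)
        with pytest.raises(SimulationError):
            fe.SimConfig(maf_range=(0.0, 0.5))


class TestGeneDrop:
    def test_mendelian_certainty(self):
        # both parents homozygous 0 -> offspring 0; parents 2 and 0 -> 1
        ped = fe.Pedigree.from_frame(
            pd.DataFrame(
                {
                    "animal": [1, 2, 3],
                    "sire": [0, 0, 1],
                    "dam": [0, 0, 2],
                    "birth_year": [0, 0, 1],
                }
            )
        )
        cfg = fe.SimConfig(n_founders=2, n_generations=1, offspring_per_mating=1, n_snps=50, seed=0)
        geno = fe.gene_drop(ped, cfg)
        child = geno.codes[2]
        both_zero = (geno.codes[0] == 0) & (geno.codes[1] == 0)
        assert (child[both_zero] == 0).all()
        opposite = (geno.codes[0] == 2) & (geno.codes[1] == 0)
        assert (child[opposite] == 1).all()

    def test_founder_relationships_near_identity(self):
        cfg = fe.SimConfig(n_founders=60, n_generations=1, offspring_per_mating=1,
                           n_snps=3000, seed=4)
        ped, _ = fe.simulate_pedigree(cfg)
        founders = [ped.ids[i] for i in range(len(ped)) if ped.is_founder[i]]
        geno = fe.gene_drop(ped, cfg)
        pos = ped.positions(founders)
        G = fe.vanraden_G(fe.GenotypeMatrix(founders, geno.codes[pos])).toarray()
        off = G[np.triu_indices_from(G, k=1)]
        assert abs(off.mean()) < 0.03
        assert abs(np.diag(G).mean() - 1.0) < 0.1


class TestBreedingValues:
    def test_zero_variance_gives_zero_bvs(self, reduced_study):
        bvs = fe.simulate_breeding_values(reduced_study.pedigree, np.zeros((2, 2)), seed=1)
        assert (bvs.to_numpy() == 0).all()

    def test_founder_variance_recovers_target(self):
        cfg = fe.SimConfig(n_founders=5000, n_generations=1, offspring_per_mating=1, seed=3)
        ped, _ = fe.simulate_pedigree(cfg)
        bvs = fe.simulate_breeding_values(ped, np.array([[1.0]]), seed=3)
        founders = ped.is_founder
        v = bvs.to_numpy()[founders].var()
        assert 0.92 < v < 1.08

    def test_midparent_correlation_is_sqrt_half(self):
        cfg = fe.SimConfig(n_founders=2000, n_generations=1, offspring_per_mating=2, seed=5)
        ped, _ = fe.simulate_pedigree(cfg)
        bvs = fe.simulate_breeding_values(ped, np.array([[1.0]]), seed=5)
        u = bvs.to_numpy()[:, 0]
        kids = np.where(~ped.is_founder)[0]
        mid = 0.5 * (u[ped.sire[kids]] + u[ped.dam[kids]])
        r = np.corrcoef(u[kids], mid)[0, 1]
        assert r == pytest.approx(np.sqrt(0.5), abs=0.04)

    def test_non_psd_rejected(self, reduced_study):
        with pytest.raises(SimulationError):
            fe.simulate_breeding_values(reduced_study.pedigree, np.array([[-1.0]]), seed=1)


class TestRecords:
    def test_noise_free_limit_dmi_equals_edmi(self):
        cfg = fe.SimConfig.reduced(
            seed=5,
            alpha_sd=0.0,
            variance_components={
                "htm": 0.0,
                "pe": 0.0,
                "animal": 0.0,
                "residual_weighted": 0.0,
                "residual_pattern": (1, 1, 1, 1, 1),
            },
        )
        study = fe.simulate_study(cfg)
        assert np.abs(study.records["dmi"] - study.records["edmi_rdc"]).max() < 1e-10

    def test_bwl_bwg_never_both_positive(self, reduced_study):
        rec = reduced_study.records
        assert not ((rec["bwl"] > 0) & (rec["bwg"] > 0)).any()

    def test_record_counts_and_week_cap(self, reduced_study):
        rec = reduced_study.records
        per_cow = rec.groupby("cow")["week"].count()
        assert (per_cow == reduced_study.config.weeks_per_cow).all()
        assert rec["week"].max() <= 44

    def test_structural_slope_one_with_zero_efficiency_variance(self):
        cfg = fe.SimConfig.reduced(
            seed=9,
            alpha_sd=0.0,
            variance_components={
                "htm": 0.0,
                "pe": 0.0,
                "animal": 0.0,
                "residual_weighted": 0.4,
                "residual_pattern": (1, 1, 1, 1, 1),
            },
        )
        study = fe.simulate_study(cfg)
        rec = study.records
        slope = np.polyfit(rec["edmi_rdc"], rec["dmi"], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)

    def test_mei_is_dmi_times_energy_density(self, reduced_study):
        rec = reduced_study.records
        assert np.allclose(rec["mei"], rec["dmi"] * reduced_study.config.energy_density)

    def test_phenotype_means_near_emulated_targets(self, reduced_study):
        rec = reduced_study.records
        means = rec[["ecm", "mbw", "bcs"]].mean()
        assert means["ecm"] == pytest.approx(29.0, abs=1.5)
        assert means["mbw"] == pytest.approx(119.7, abs=3.0)
        assert means["bcs"] == pytest.approx(3.17, abs=0.15)

    def test_pasture_gap_removes_summer_weeks(self):
        # 28-week lactations so autumn calvers actually reach the summer months
        cfg = fe.SimConfig.reduced(seed=2, pasture_gap=True, weeks_per_cow=28)
        study = fe.simulate_study(cfg)
        per_cow = study.records.groupby("cow")["week"].count()
        assert per_cow.min() < cfg.weeks_per_cow  # some cows have gaps


class TestStudy:
    def test_full_determinism(self):
        s1 = fe.simulate_study(fe.SimConfig.reduced(seed=7))
        s2 = fe.simulate_study(fe.SimConfig.reduced(seed=7))
        pd.testing.assert_frame_equal(s1.records, s2.records)
        assert (s1.genotypes.codes == s2.genotypes.codes).all()
        assert s1.genotyped_ids == s2.genotyped_ids

    def test_cows_in_pedigree_and_genotyped_subset(self, reduced_study):
        ped_ids = set(reduced_study.pedigree.ids)
        assert set(reduced_study.records["cow"]) <= ped_ids
        assert set(reduced_study.genotyped_ids) <= ped_ids

    def test_default_scale_emulates_study_conditions(self):
        # founder dams × (2 + offspring-chain) females -> ~792 recorded cows,
        # each with 28 weekly records across 4 herds and a 24-year window
        cfg = fe.SimConfig()
        dams = cfg.n_founders // 2
        expected_cows = dams * 2 + dams * 2 * 2  # generation 1 + generation 2
        assert expected_cows == pytest.approx(791, abs=10)
        assert cfg.weeks_per_cow == 28 and cfg.n_herds == 4 and cfg.n_years == 24
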