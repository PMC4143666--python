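import numpy as np
import pandas as pd
import pytest

import kinlong as kl
from kinlong import gio
from kinlong.pheno_prep import mean_over_visits

from conftest import SEED, make_pedigree


class TestBuildPedigrees:
    def test_sibship_counts(self):
        ped = kl.build_pedigrees(kl.SimConfig(n_pedigrees=125, pedigree_template="sibship(4)"))
        assert ped.n_individuals == 750           # 500 offspring + 250 founder parents
        assert len(ped.founders()) == 250
        assert len(ped.pedigree_ids) == 125

    def test_three_generation_blocks(self):
        cfg = kl.SimConfig(n_pedigrees=20, pedigree_template="three_generation")
        K = kl.kinship_matrix(kl.build_pedigrees(cfg))
        assert len(K.blocks) == 20

    def test_unknown_template_errors(self):
        with pytest.raises(ValueError, match="template"):
            kl.build_pedigrees(kl.SimConfig(pedigree_template="clan(9)"))

    def test_seed_determinism(self):
        cfg = kl.SimConfig(n_pedigrees=6, pedigree_template="nuclear(3)", seed=5)
        assert kl.build_pedigrees(cfg) == kl.build_pedigrees(cfg)


class TestGeneDrop:
    def test_maf_zero_gives_zero_dosage(self, trio):
        d = kl.gene_drop(trio, 0.0, np.random.default_rng(SEED))
        assert np.all(d == 0)

    def test_founder_dosage_mean(self):
        ped = make_pedigree([("P", "f", None, None, "male")])
        d = kl.gene_drop(ped, np.full(100_000, 0.3), np.random.default_rng(SEED))
        assert d.mean() == pytest.approx(0.6, abs=0.01)

    def test_sibling_dosage_correlation_is_half(self):
        ped = kl.build_pedigrees(kl.SimConfig(n_pedigrees=1, pedigree_template="sibship(2)"))
        d = kl.gene_drop(ped, np.full(100_000, 0.3), np.random.default_rng(SEED))
        sibs = [i for i, iid in enumerate(ped.df["iid"]) if "_o" in iid]
        r = np.corrcoef(d[sibs[0]], d[sibs[1]])[0, 1]
        assert r == pytest.approx(0.5, abs=0.02)   # additive correlation = 2*phi

    def test_mendelian_consistency(self, small_study):
        ped, _, geno, *_ = small_study
        pos = {iid: i for i, iid in enumerate(geno.ids)}
        for row in ped.df.itertuples(index=False):
            if row.father is None:
                continue
            kid = geno.dosages[pos[row.iid]]
            pa = geno.dosages[pos[row.father]]
            ma = geno.dosages[pos[row.mother]]
            # a child allele count is bounded by what the parents carry
            assert np.all(kid <= np.minimum(pa, 1) + np.minimum(ma, 1) + 0)
            assert np.all(kid >= np.maximum(pa - 1, 0) + np.maximum(ma - 1, 0))


class TestPolygenic:
    def test_zero_variance(self, trio):
        K = kl.kinship_matrix(trio)
        assert np.all(kl.simulate_polygenic(K, 0.0, np.random.default_rng(1)) == 0)

    def test_singletons_iid_scaled_by_diagonal(self):
        ped = make_pedigree([(f"P{i}", f"s{i}", None, None, "male") for i in range(2000)])
        K = kl.kinship_matrix(ped)
        g = kl.simulate_polygenic(K, 2.0, np.random.default_rng(SEED))
        assert g.var() == pytest.approx(2.0 * K.values[0, 0], rel=0.1)

    def test_sib_pair_empirical_covariance(self):
        ped = kl.build_pedigrees(kl.SimConfig(n_pedigrees=1, pedigree_template="sibship(2)"))
        K = kl.kinship_matrix(ped)
        rng = np.random.default_rng(SEED)
        draws = np.array([kl.simulate_polygenic(K, 1.5, rng) for _ in range(10_000)])
        emp = np.cov(draws.T)
        assert np.allclose(emp, 1.5 * K.values, atol=0.12)


class TestLongitudinal:
    def test_noise_free_trait_is_linear_in_covariates(self):
        cfg = kl.SimConfig(
            n_pedigrees=3, pedigree_template="sibship(2)",
            var_polygenic=0.0, var_person=0.0, var_occasion=0.0, seed=4,
        )
        _, _, _, pheno, _ = kl.simulate_dataset(cfg, n_snps=1)
        b = cfg.beta_covars
        pred = (
            b["intercept"] + b["age"] * pheno["age"]
            + b["male"] * (pheno["sex"] == 1) + b["smoke"] * pheno["smoke"]
        )
        assert np.allclose(pheno["trait"], pred)

    def test_visit_mean_residual_variance_identity(self):
        """Averaging v visits keeps person-level variance, shrinks occasion noise by v."""
        cfg = kl.SimConfig(
            n_pedigrees=400, pedigree_template="sibship(4)", n_visits=4, seed=SEED,
            beta_covars={"intercept": 0.0, "age": 0.0, "male": 0.0, "smoke": 0.0},
        )
        ped, K, geno, pheno, truth = kl.simulate_dataset(cfg, n_snps=1)
        mm = mean_over_visits(pheno)
        v_kin, v_resid = truth.implied_person_level_components(4)
        # total person-mean variance = var_g * diag(K) + var_a + var_e/4
        expected = v_kin * 1.0 + v_resid
        assert mm["trait"].var() == pytest.approx(expected, rel=0.12)

    def test_person_visit_total_variance(self):
        cfg = kl.SimConfig(
            n_pedigrees=600, pedigree_template="sibship(2)", n_visits=2, seed=SEED + 1,
            beta_covars={"intercept": 0.0, "age": 0.0, "male": 0.0, "smoke": 0.0},
        )
        _, _, _, pheno, truth = kl.simulate_dataset(cfg, n_snps=1)
        total = truth.var_polygenic + truth.var_person + truth.var_occasion
        assert pheno["trait"].var() == pytest.approx(total, rel=0.1)

    def test_ages_advance_by_gap(self, small_study):
        _, _, _, pheno, _ = small_study
        one = pheno[pheno["individual_id"] == pheno["individual_id"].iloc[0]]
        assert np.allclose(np.diff(one["age"]), 5.0)

    def test_dropout_truncates_followup(self):
        cfg = kl.SimConfig(n_pedigrees=100, pedigree_template="sibship(2)",
                           dropout_rate=0.3, seed=9)
        _, _, _, pheno, _ = kl.simulate_dataset(cfg, n_snps=1)
        counts = pheno.groupby("individual_id")["visit"].agg(["size", "max"])
        assert (counts["size"] == counts["max"]).all()   # no gaps, only truncation
        assert counts["size"].min() == 1 and counts["size"].max() == 4

    def test_dataset_determinism(self):
        cfg = kl.SimConfig(n_pedigrees=4, pedigree_template="three_generation", seed=77)
        a = kl.simulate_dataset(cfg, n_snps=3)
        b = kl.simulate_dataset(cfg, n_snps=3)
        assert a[0] == b[0]
        assert np.array_equal(a[2].dosages, b[2].dosages)
        pd.testing.assert_frame_equal(a[3], b[3])


class TestMedication:
    def test_infinite_threshold_is_identity(self, small_study):
        *_, pheno, _ = small_study
        out = kl.apply_medication(pheno, float("inf"), 10.0)
        assert (out["medicated"] == 0).all()
        assert np.array_equal(out["trait"], pheno["trait"])

    def test_everyone_flagged_below_any_trait(self, small_study):
        *_, pheno, _ = small_study
        out = kl.apply_medication(pheno, float("-inf"), 10.0)
        assert (out["medicated"] == 1).all()
        assert np.allclose(out["trait"], pheno["trait"] - 10.0)

    def test_flagged_fraction_matches_quantile(self):
        cfg = kl.SimConfig(n_pedigrees=500, pedigree_template="sibship(2)", seed=3)
        *_, pheno, truth = kl.simulate_dataset(cfg, n_snps=1)
        t90 = np.quantile(pheno["trait"], 0.9)
        out = kl.apply_medication(pheno, t90, 10.0, truth=truth)
        assert out["medicated"].mean() == pytest.approx(0.10, abs=0.01)
        # latent values retained
        assert truth.latent_trait[
            (pheno["individual_id"].iloc[0], int(pheno["visit"].iloc[0]))
        ] == pytest.approx(pheno["trait"].iloc[0])


class TestWriters:
    def test_vcf_roundtrip(self, tmp_path, small_study):
        _, _, geno, *_ = small_study
        path = tmp_path / "g.vcf"
        gio.write_vcf(geno, path)
        back = gio.read_vcf(path)
        assert back.ids == geno.ids and back.snp_ids == geno.snp_ids
        assert np.allclose(back.dosages, geno.dosages, atol=1e-4)

    def test_dosage_tsv_roundtrip(self, tmp_path, small_study):
        _, _, geno, *_ = small_study
        path = tmp_path / "g.tsv"
        gio.write_dosage_tsv(geno, path)
        back = gio.read_dosage_tsv(path)
        assert np.allclose(back.dosages, geno.dosages, atol=1e-5)

    def test_pheno_tsv_roundtrip(self, tmp_path, small_study):
        *_, pheno, _ = small_study
        path = tmp_path / "p.tsv"
        kl.simdata.write_pheno_tsv(pheno, path)
        back = kl.simdata.read_pheno_tsv(path)
        assert len(back) == len(pheno)
        assert np.allclose(back["trait"], pheno["trait"], atol=1e-5)

    def test_truth_json(self, tmp_path, small_study):
        *_, truth = small_study
        truth.to_json(tmp_path / "t.json")
        import json

        d = json.loads((tmp_path / "t.json").read_text())
        assert d["var_occasion"] == truth.var_occasion


def test_ld_twins_hit_target_r2(small_study):
    _, _, geno, *_ = small_study
    twinned = kl.with_ld_twins(geno, 0.5, np.random.default_rng(SEED))
    assert twinned.n_snps == 2 * geno.n_snps
    r2 = []
    for j in range(0, twinned.n_snps, 2):
        r = np.corrcoef(twinned.dosages[:, j], twinned.dosages[:, j + 1])[0, 1]
        r2.append(r * r)
    assert np.median(r2) == pytest.approx(0.5, abs=0.1)
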