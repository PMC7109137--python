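import numpy as np
import pytest

import gblupkit as gk
from gblupkit.errors import SimulationError
from gblupkit.simulate import _gamete


def small_cfg(**kw):
    defaults = dict(
        n_founders=30,
        n_chromosomes=4,
        n_snps=400,
        progeny_per_cross=5,
        seed=101,
        traits=(gk.TraitConfig("T", 0.4, pe_fraction=0.1, n_qtl=60),),
    )
    defaults.update(kw)
    return gk.SimulationConfig(**defaults)


class TestSimulateFounders:
    def test_mean_dosage_at_half_maf(self):
        cfg = small_cfg(n_founders=400, maf_range=(0.5, 0.5), n_snps=300)
        founders, _ = gk.simulate_founders(cfg)
        mean = founders.dosage.mean(axis=0)
        se = np.sqrt(0.5 / 400)  # binomial(2, 0.5) variance = 0.5
        assert np.all(np.abs(mean - 1.0) < 3 * se + 0.08)
        assert abs(float(mean.mean()) - 1.0) < 3 * se / np.sqrt(300) + 0.01

    def test_deterministic_with_seed(self):
        a, _ = gk.simulate_founders(small_cfg())
        b, _ = gk.simulate_founders(small_cfg())
        np.testing.assert_array_equal(a.dosage, b.dosage)
        assert a.sites == b.sites

    def test_zero_snps_errors(self):
        with pytest.raises(SimulationError):
            gk.simulate_founders(small_cfg(n_snps=0))

    def test_infeasible_spacing_errors(self):
        with pytest.raises(SimulationError, match="spacing"):
            gk.simulate_founders(small_cfg(n_snps=100, chromosome_length_bp=40))

    def test_positions_spaced_at_least_two(self):
        founders, _ = gk.simulate_founders(small_cfg())
        by_chrom = {}
        for s in founders.sites:
            by_chrom.setdefault(s.chrom, []).append(s.pos)
        for positions in by_chrom.values():
            assert np.all(np.diff(positions) >= 2)


class TestSimulatePedigree:
    def test_expected_cross_and_progeny_counts(self):
        cfg = gk.SimulationConfig(
            n_founders=274, n_chromosomes=2, n_snps=40, progeny_per_cross=18,
            seed=5, traits=(gk.TraitConfig("T", 0.3, n_qtl=10),),
        )
        founders = [f"P{i:04d}" for i in range(274)]
        ped = gk.simulate_pedigree(cfg, founders)
        n_prog = len(ped.nonfounders)
        assert 4900 <= n_prog <= 5000  # 274 crosses x 18
        assert n_prog == 274 * 18

    def test_no_selfing(self):
        cfg = small_cfg()
        ped = gk.simulate_pedigree(cfg, [f"F{i}" for i in range(10)])
        for _, sire, dam in ped.records:
            if sire or dam:
                assert sire != dam

    def test_deterministic(self):
        cfg = small_cfg()
        ids = [f"F{i}" for i in range(12)]
        assert gk.simulate_pedigree(cfg, ids).records == gk.simulate_pedigree(cfg, ids).records

    def test_bad_mean_crosses_errors(self):
        with pytest.raises(SimulationError):
            gk.simulate_pedigree(small_cfg(mean_crosses_per_parent=0.0), ["a", "b"])


class TestGeneDrop:
    def test_zero_length_map_transmits_whole_haplotypes(self):
        cfg = small_cfg(
            chromosome_length_morgans=0.0, n_chromosomes=1, n_snps=50,
            traits=(gk.TraitConfig("T", 0.4, n_qtl=20),),
        )
        founders, haps = gk.simulate_founders(cfg)
        rng = np.random.default_rng(0)
        positions = np.array([s.pos for s in founders.sites], dtype=float)
        parent = haps[founders.individual_ids[0]]
        for _ in range(5):
            g = _gamete(parent, [slice(0, 50)], positions, cfg, rng)
            assert np.array_equal(g, parent[0]) or np.array_equal(g, parent[1])

    def test_unhaplotyped_parent_errors(self):
        cfg = small_cfg()
        founders, haps = gk.simulate_founders(cfg)
        ped = gk.PedigreeTable((("X", "", ""), ("Y", "", ""), ("Z", "X", "Y")))
        with pytest.raises(SimulationError):
            gk.gene_drop(haps, ped, cfg, founders.sites)

    def test_pairwise_genomic_relationships(self):
        # parent-offspring ~0.5, full sibs ~0.5, half sibs ~0.25 on average
        cfg = gk.SimulationConfig(
            n_founders=40, n_chromosomes=5, n_snps=2000, progeny_per_cross=6,
            seed=77, traits=(gk.TraitConfig("T", 0.3, n_qtl=30),),
        )
        study = gk.simulate_study(cfg)
        G, _ = gk.filter_sites(study.genotypes, max_missing_frac=1.0, min_maf=1e-9,
                               remove_adjacent=False)
        G = gk.gmat_vanraden(G)
        gdf = G.to_frame()
        ped = study.pedigree
        po, fs, hs = [], [], []
        nonf = ped.nonfounders
        for i, child in enumerate(nonf):
            s, d = ped.parents(child)
            po.append(gdf.loc[child, s])
            for other in nonf[i + 1 :]:
                s2, d2 = ped.parents(other)
                shared = len({s, d} & {s2, d2})
                if shared == 2:
                    fs.append(gdf.loc[child, other])
                elif shared == 1:
                    hs.append(gdf.loc[child, other])
        assert abs(np.mean(po) - 0.5) < 0.1
        assert abs(np.mean(fs) - 0.5) < 0.1
        if hs:
            assert abs(np.mean(hs) - 0.25) < 0.1


class TestSimulatePhenotypes:
    def test_regression_slope_on_true_bv(self):
        cfg = small_cfg(n_founders=100, progeny_per_cross=10, n_snps=600,
                        traits=(gk.TraitConfig("T", 0.4, pe_fraction=0.1, n_qtl=100),))
        study = gk.simulate_study(cfg)
        df = study.phenotypes.for_trait("T")
        bv = study.truth.true_bv["T"]
        x = bv.loc[df["individual"]].to_numpy()
        slope = np.polyfit(x, df["value"].to_numpy(), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_noise_free_limit_is_exact(self):
        cfg = small_cfg(traits=(gk.TraitConfig("T", 1.0, pe_fraction=0.0, n_qtl=50,
                                               mean=3.0, year_effects=(0.5, -0.5)),))
        study = gk.simulate_study(cfg)
        df = study.phenotypes.for_trait("T")
        bv = study.truth.true_bv["T"]
        ye = {1: 0.5, 2: -0.5}
        expected = 3.0 + df["year"].map(ye).to_numpy() + bv.loc[df["individual"]].to_numpy()
        np.testing.assert_allclose(df["value"].to_numpy(), expected, atol=1e-12)

    def test_realized_h2_matches_target(self):
        cfg = small_cfg(n_founders=120, progeny_per_cross=20, n_snps=600,
                        traits=(gk.TraitConfig("T", 0.3, pe_fraction=0.0, n_qtl=80),))
        study = gk.simulate_study(cfg)
        assert len(study.pedigree.ids) >= 2000
        df = study.phenotypes.for_trait("T")
        year1 = df[df["year"] == 1]
        bv = study.truth.true_bv["T"].loc[year1["individual"]]
        realized = float(np.var(bv) / np.var(year1["value"]))
        assert abs(realized - 0.3) < 0.05

    def test_negative_residual_variance_rejected(self):
        with pytest.raises(SimulationError):
            gk.TraitConfig("T", 0.8, pe_fraction=0.3)

    def test_truth_components_recorded(self):
        study = gk.simulate_study(small_cfg())
        comp = study.truth.realized_components.loc["T"]
        pv = study.config.traits[0].phenotypic_variance
        assert comp["var_a"] == pytest.approx(0.4 * pv, rel=1e-9)
        assert comp["h2_target"] == 0.4


class TestRelatedPanelMode:
    def test_recorded_pedigree_hides_base_generation(self):
        cfg = small_cfg(n_base_founders=10)
        study = gk.simulate_study(cfg)
        assert set(study.pedigree.founders) == set(study.parent_ids)
        assert not any(i.startswith("B") for i in study.pedigree.ids)
        assert any(i.startswith("B") for i in study.true_pedigree.ids)
        # the panel is genomically related despite founder-coded pedigree
        rows = np.array([study.genotypes.individual_ids.index(p) for p in study.parent_ids])
        gp, _ = gk.filter_sites(study.genotypes.subset(individuals=rows),
                                max_missing_frac=1.0, min_maf=1e-9, remove_adjacent=False)
        G = gk.gmat_vanraden(gp).values
        off = G[~np.eye(len(rows), dtype=bool)]
        assert off.max() > 0.3  # sib pairs exist

    def test_phenotypes_only_for_recorded_individuals(self):
        study = gk.simulate_study(small_cfg(n_base_founders=10))
        assert set(study.phenotypes.individuals) <= set(study.pedigree.ids)


class TestDefaultStudy:
    @pytest.fixture(scope="class")
    @classmethod
    def written(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("study")
        study = gk.default_study(
            3, out_dir=out, n_founders=25, n_snps=300, n_chromosomes=3,
            progeny_per_cross=3,
        )
        return study, out

    def test_eight_traits(self, written):
        study, _ = written
        assert len(study.config.traits) == 8
        assert {t.name for t in study.config.traits} == set(study.phenotypes.traits)

    def test_roundtrips_through_readers(self, written):
        study, out = written
        ped = gk.read_pedigree(out / "pedigree.csv")
        assert ped.records == study.pedigree.records
        phen = gk.read_phenotypes(out / "phenotypes.csv")
        assert len(phen.frame) == len(study.phenotypes.frame)
        gv = gk.read_genotypes(out / "genotypes.vcf", "vcf")
        np.testing.assert_array_equal(gv.dosage, study.genotypes.dosage)
        gt = gk.read_genotypes(out / "genotypes.tsv", "dosage_tsv")
        np.testing.assert_array_equal(gt.dosage, study.genotypes.dosage)

    def test_fixed_seed_byte_identical(self, tmp_path):
        kw = dict(n_founders=12, n_snps=80, n_chromosomes=2, progeny_per_cross=2)
        gk.default_study(9, out_dir=tmp_path / "a", **kw)
        gk.default_study(9, out_dir=tmp_path / "b", **kw)
        for name in ("pedigree.csv", "phenotypes.csv", "genotypes.vcf", "genotypes.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_all_randomness_from_seed(self):
        kw = dict(n_founders=12, n_snps=80, n_chromosomes=2, progeny_per_cross=2)
        s1 = gk.default_study(9, **kw)
        s2 = gk.default_study(10, **kw)
        assert not np.array_equal(s1.genotypes.dosage, s2.genotypes.dosage)
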