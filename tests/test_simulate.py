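from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from concordia import (
    CtSimConfig,
    SimulationConfig,
    ValidationError,
    generate_compendium,
    generate_ct_experiment,
    generate_two_tissue_study,
    welch_contrast,
    write_bundle,
)
from concordia.io import write_gmt


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_genes": 0},
        {"module_size": 0},
        {"noise_sd": 0.0},
        {"background_de_rate": 1.0},
        {"n_driver_treatments": 9, "n_treatments": 8},
        {"module_size": 500, "n_genes": 400},
        {"disjoint_signatures": True, "module_size": 100, "n_treatments": 10,
         "n_genes": 500},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SimulationConfig(**kwargs).validate()

    def test_ct_config_validation(self):
        with pytest.raises(ValidationError):
            CtSimConfig(n_replicates=1).validate()
        with pytest.raises(ValidationError):
            CtSimConfig(replicate_sd=-0.1).validate()


class TestCompendium:
    def test_default_shape_42_treatments_of_100_genes(self):
        cfg = SimulationConfig(seed=5)
        comp = generate_compendium(cfg)
        assert len(comp) == 42
        for entry in comp:
            assert len(entry.induced) + len(entry.repressed) == 100
            assert not entry.induced & entry.repressed
        # default direction split: 70% induced
        assert all(len(e.induced) == 70 for e in comp)

    def test_saturation_single_treatment_covers_universe(self):
        cfg = SimulationConfig(n_genes=50, n_treatments=1,
                               n_driver_treatments=1, module_size=50, seed=1)
        (entry,) = generate_compendium(cfg)
        assert entry.induced | entry.repressed == set(cfg.gene_ids)

    def test_same_seed_gives_byte_identical_gmt(self, tmp_path):
        cfg = SimulationConfig(n_genes=300, n_treatments=6,
                               module_size=30, seed=9)
        p1, p2 = tmp_path / "a.gmt", tmp_path / "b.gmt"
        write_gmt(generate_compendium(cfg), p1)
        write_gmt(generate_compendium(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_disjoint_switch_partitions_universe(self):
        cfg = SimulationConfig(n_genes=400, n_treatments=8, module_size=50,
                               disjoint_signatures=True, seed=2)
        comp = generate_compendium(cfg)
        seen: set[str] = set()
        for e in comp:
            members = e.induced | e.repressed
            assert not members & seen
            seen |= members


class TestTwoTissueStudy:
    def test_truth_bookkeeping(self, small_cfg, small_study):
        truth = small_study.truth
        assert truth["driver_ids"] == ["IFN-g", "TNF-a"]
        planted = truth["planted_genes"]
        assert set(planted) <= set(small_study.tissue1.gene_ids)
        driver_members = set()
        for d in truth["driver_ids"]:
            entry = small_study.compendium.get(d)
            driver_members |= entry.induced | entry.repressed
        assert set(planted) == driver_members
        # induced genes have positive true effect in both tissues
        for tissue in ("tissue1", "tissue2"):
            effects = truth["true_effects"][tissue]
            for gene, direction in planted.items():
                assert np.sign(effects[gene]) == direction

    def test_effect_encoding_recovered_from_matrix(self, small_cfg, small_study):
        cfg = small_cfg
        n = cfg.n_samples_per_group_tissue1
        m = small_study.tissue1
        case = m.group_values("case").mean(axis=1)
        ctrl = m.group_values("control").mean(axis=1)
        diff = dict(zip(m.gene_ids, case - ctrl))
        tol = 4 * cfg.noise_sd / np.sqrt(n)
        for gene, direction in small_study.truth["planted_genes"].items():
            assert abs(diff[gene] - direction * cfg.shared_effect_lfc) < tol

    def test_null_planting_yields_false_positive_rate_only(self):
        cfg = SimulationConfig(n_genes=1000, n_treatments=6, module_size=50,
                               shared_effect_lfc=0.0, background_de_rate=0.0,
                               n_samples_per_group_tissue1=8,
                               n_samples_per_group_tissue2=8, seed=21)
        study = generate_two_tissue_study(cfg)
        assert study.truth["driver_ids"] == ["IFN-g", "TNF-a"]
        contrast = welch_contrast(study.tissue1)
        # BH at q<0.05 under the global null: expect ~0 discoveries
        assert (contrast["q"] < 0.05).sum() <= 2
        assert stats.kstest(contrast["p"], "uniform").pvalue > 0.01

    def test_determinism_same_seed_same_study(self, small_cfg):
        s1 = generate_two_tissue_study(small_cfg)
        s2 = generate_two_tissue_study(small_cfg)
        assert s1.tissue1.values.equals(s2.tissue1.values)
        assert s1.tissue2.values.equals(s2.tissue2.values)
        assert s1.truth == s2.truth
        assert s1.annotation.equals(s2.annotation)

    def test_different_seed_changes_data(self, small_cfg):
        other = generate_two_tissue_study(replace(small_cfg, seed=99))
        base = generate_two_tissue_study(small_cfg)
        assert not base.tissue1.values.equals(other.tissue1.values)

    def test_stimulation_profiles_cover_drivers(self, small_study):
        assert set(small_study.stimulation_profiles) == {"IFN-g", "TNF-a"}
        prof = small_study.stimulation_profiles["IFN-g"]
        entry = small_study.compendium.get("IFN-g")
        induced_mean = prof.values.loc[sorted(entry.induced)].mean()
        assert induced_mean > 0.5  # signature genes carry the planted shift


class TestCtExperiment:
    def test_no_effect_config_gives_fold_one_everywhere(self):
        from concordia import ddct_fold

        cfg = CtSimConfig(effect_a_dct=0, effect_b_dct=0, interaction_dct=0,
                          replicate_sd=0.0, seed=1)
        table = generate_ct_experiment(cfg)
        for cond in (cfg.condition_a, cfg.condition_b, cfg.combo_condition):
            res = ddct_fold(table, cfg.target_gene, cfg.reference_gene,
                            cond, cfg.control_condition)
            assert res.fold == pytest.approx(1.0)

    def test_planted_shift_of_4_cycles_gives_fold_16(self):
        from concordia import ddct_fold

        cfg = CtSimConfig(effect_a_dct=4.0, replicate_sd=0.0, seed=1)
        table = generate_ct_experiment(cfg)
        res = ddct_fold(table, cfg.target_gene, cfg.reference_gene,
                        cfg.condition_a, cfg.control_condition)
        assert res.fold == pytest.approx(16.0, rel=1e-12)

    def test_layout_and_determinism(self):
        cfg = CtSimConfig(seed=4)
        t1, t2 = generate_ct_experiment(cfg), generate_ct_experiment(cfg)
        assert t1.equals(t2)
        assert set(t1["condition"]) == {
            "control", "IFN-g", "TNF-a", "IFN-g+TNF-a"
        }
        counts = t1.groupby(["condition", "gene"]).size()
        assert (counts == cfg.n_replicates).all()


class TestBundle:
    def test_bundle_files_written(self, tmp_path, small_study):
        out = write_bundle(small_study, tmp_path / "bundle",
                           ct_table=generate_ct_experiment(CtSimConfig(seed=1)))
        for name in ("tissue1.tsv", "tissue1_groups.tsv", "tissue2.tsv",
                     "tissue2_groups.tsv", "compendium.gmt", "annotation.tsv",
                     "truth.json", "ct.tsv"):
            assert (out / name).exists()
        gmt_lines = (out / "compendium.gmt").read_text().strip().split("\n")
        assert len(gmt_lines) == 2 * 8
        assert (out / "profiles" / "IFN-g.tsv").exists()

    def test_refuses_non_empty_dir_without_force(self, tmp_path, small_study):
        target = tmp_path / "bundle"
        target.mkdir()
        (target / "junk.txt").write_text("x")
        with pytest.raises(ValidationError, match="force"):
            write_bundle(small_study, target)
        write_bundle(small_study, target, force=True)
        assert (target / "truth.json").exists()
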