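import json

import numpy as np
import pandas as pd
import pytest

from connectosync import reach_probability as rp
from connectosync import synthetic_data as syn
from connectosync.exceptions import ConfigError


class TestConfigValidation:
    def test_fraction_out_of_range(self):
        with pytest.raises(ConfigError):
            syn.SyntheticConfig(planted_connections=[("t", 2, 1.5)])

    def test_sync_rho_must_be_in_open_unit_interval(self):
        for rho in (0.0, 1.0, -0.2):
            with pytest.raises(ConfigError):
                syn.SyntheticConfig(
                    planted_sync=[
                        syn.PlantedSync("region01", "region02", 5, 5, rho)
                    ]
                )

    def test_block_larger_than_region_rejected(self):
        with pytest.raises(ConfigError):
            syn.SyntheticConfig(
                n_genes_per_region=10,
                planted_sync=[
                    syn.PlantedSync("region01", "region02", 50, 50, 0.5)
                ],
            )

    def test_planted_fractions_summing_over_one_rejected(self):
        cfg = syn.SyntheticConfig(
            planted_connections=[("tract01", 2, 0.7), ("tract01", 3, 0.6)]
        )
        labels = syn.generate_label_volume(cfg)
        with pytest.raises(ConfigError, match="tract01"):
            syn.generate_tract_volumes(cfg, labels)


class TestLabelVolume:
    def test_two_rois_on_minimal_grid(self):
        cfg = syn.SyntheticConfig(grid_shape=(8, 8, 8), n_rois=2)
        labels = syn.generate_label_volume(cfg)
        assert set(np.unique(labels.values)) == {0, 1, 2, 3}

    def test_every_roi_has_nonempty_boundary_mask(self, label_volume):
        for roi in label_volume.roi_labels:
            assert rp.boundary_mask(label_volume, roi).any()

    def test_grid_too_small_names_roi(self):
        # 8x8x8 offers 16 ROI cells; the 17th ROI (label 18) cannot fit
        with pytest.raises(ConfigError, match="18"):
            syn.generate_label_volume(
                syn.SyntheticConfig(grid_shape=(8, 8, 8), n_rois=20)
            )

    def test_determinism(self):
        cfg = syn.SyntheticConfig(seed=1)
        a = syn.generate_label_volume(cfg)
        b = syn.generate_label_volume(cfg)
        assert np.array_equal(a.values, b.values)


class TestTractVolumes:
    def test_planted_connection_outranks_unplanted(
        self, small_config, label_volume, tract_volumes
    ):
        row = rp.reach_probability(tract_volumes[0], label_volume)
        assert row[2] > row[4]  # planted (tract01, 2) vs unplanted ROI 4

    def test_leak_zero_means_exact_zero_elsewhere(
        self, small_config, label_volume, tract_volumes
    ):
        planted = {
            (t, r) for t, r, _ in small_config.planted_connections
        }
        for tract in tract_volumes:
            for roi in label_volume.roi_labels:
                if (tract.tract_id, roi) in planted:
                    continue
                mask = rp.boundary_mask(label_volume, roi)
                assert tract.counts[mask].sum() == 0

    def test_leak_places_mass_on_unplanted_rois(self, small_config):
        cfg = syn.SyntheticConfig(
            **{
                **vars(small_config),
                "leak_rate": 0.05,
                "planted_sync": small_config.planted_sync,
            }
        )
        labels = syn.generate_label_volume(cfg)
        tracts = syn.generate_tract_volumes(cfg, labels)
        planted = {(t, r) for t, r, _ in cfg.planted_connections}
        leaked = 0
        for tract in tracts:
            for roi in labels.roi_labels:
                if (tract.tract_id, roi) in planted:
                    continue
                leaked += tract.counts[rp.boundary_mask(labels, roi)].sum()
        assert leaked > 0

    def test_total_mass_preserved(self, small_config, tract_volumes):
        for tract in tract_volumes:
            assert tract.counts.sum() == small_config.total_paths

    def test_determinism(self, small_config, label_volume):
        a = syn.generate_tract_volumes(small_config, label_volume)
        b = syn.generate_tract_volumes(small_config, label_volume)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.counts, tb.counts)


class TestRegionExpression:
    def test_planted_block_has_requested_correlation(self, small_config):
        expr_set, truth = syn.generate_region_expression(small_config)
        block = truth.sync_blocks[0]
        a = expr_set.expression[block["region_a"]].loc[block["genes_a"][0]]
        b = expr_set.expression[block["region_b"]].loc[block["genes_b"][0]]
        r = np.corrcoef(a, b)[0, 1]
        assert r > 0.7  # planted 0.9 before covariate noise

    def test_unplanted_pairs_uncorrelated(self, small_config):
        expr_set, _ = syn.generate_region_expression(small_config)
        a = expr_set.expression["region03"].loc["G0000"]
        b = expr_set.expression["region04"].loc["G0000"]
        # covariate confounding induces a small shared component only
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.5

    def test_no_missing_values(self, small_config):
        expr_set, _ = syn.generate_region_expression(small_config)
        for mat in expr_set.expression.values():
            assert mat.notna().all().all()
        assert expr_set.covariates.notna().all().all()

    def test_determinism(self, small_config):
        a, _ = syn.generate_region_expression(small_config)
        b, _ = syn.generate_region_expression(small_config)
        for region in a.expression:
            pd.testing.assert_frame_equal(
                a.expression[region], b.expression[region]
            )

    def test_truth_carries_block_membership(self, small_config):
        _, truth = syn.generate_region_expression(small_config)
        assert len(truth.sync_blocks) == 2
        assert len(truth.sync_blocks[0]["genes_a"]) == 20


class TestPhenotypes:
    def test_columns_and_coding(self, phenotypes, small_config):
        assert set(phenotypes.diagnosis.unique()) <= {"CN", "MCI", "Dementia"}
        for tract in small_config.pheno_tracts:
            for m in small_config.measures:
                assert f"{tract}:{m}" in phenotypes.columns

    def test_planted_effect_visible(self, phenotypes):
        means = phenotypes.groupby("diagnosis")["tract01:FA"].mean()
        assert means["Dementia"] > means["CN"] + 1.0

    def test_determinism(self, small_config):
        a = syn.generate_subject_phenotypes(small_config)
        b = syn.generate_subject_phenotypes(small_config)
        pd.testing.assert_frame_equal(a, b)


class TestBloodDataset:
    def test_single_probe_gene_is_identity_after_collapse(self, small_config):
        from connectosync.blood_association import mean_max_collapse

        cfg = syn.SyntheticConfig(
            **{**vars(small_config), "n_probes_per_gene": (1, 1)}
        )
        ds, _ = syn.generate_blood_dataset(cfg)
        genes = mean_max_collapse(ds.probes, ds.probe_map)
        assert len(genes) == len(ds.probes)
        lookup = ds.probe_map.set_index("gene")["probe_id"]
        for gene in genes.index:
            np.testing.assert_array_equal(
                genes.loc[gene].to_numpy(),
                ds.probes.loc[lookup[gene]].to_numpy(),
            )

    def test_unknown_gene_set_rejected(self, small_config):
        cfg_kwargs = {**vars(small_config)}
        cfg_kwargs["geneset_effect"] = ("no_such_set", "tract01:FA", 1.0)
        with pytest.raises(ConfigError):
            syn.generate_blood_dataset(syn.SyntheticConfig(**cfg_kwargs))

    def test_determinism(self, small_config):
        a, _ = syn.generate_blood_dataset(small_config)
        b, _ = syn.generate_blood_dataset(small_config)
        pd.testing.assert_frame_equal(a.probes, b.probes)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)


class TestPersistence:
    def test_write_dataset_roundtrip(self, small_config, tmp_path):
        import nibabel as nib

        paths = syn.write_dataset(small_config, tmp_path)
        labels = np.asarray(nib.load(paths["labels"]).dataobj)
        assert labels.shape == small_config.grid_shape
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert set(truth) == {
            "connections", "sync_blocks", "diagnosis_beta", "geneset",
        }
        expr = pd.read_csv(
            paths["expression:region01"], sep="\t", index_col="gene"
        )
        assert expr.shape == (
            small_config.n_genes_per_region,
            small_config.n_subjects,
        )

    def test_yaml_config_roundtrip(self, tmp_path):
        cfg_file = tmp_path / "cfg.yaml"
        cfg_file.write_text(
            "seed: 3\n"
            "n_rois: 4\n"
            "planted_connections:\n"
            "  - [tract01, 2, 0.4]\n"
            "planted_sync:\n"
            "  - {region_a: region01, region_b: region02,"
            " n_genes_a: 5, n_genes_b: 5, rho: 0.8}\n"
            "diagnosis_effects:\n"
            "  'L-CAB:FA': 0.5\n"
        )
        cfg = syn.config_from_yaml(cfg_file)
        assert cfg.seed == 3
        assert cfg.planted_connections == [("tract01", 2, 0.4)]
        assert cfg.diagnosis_effects == {("L-CAB", "FA"): 0.5}

    def test_unknown_yaml_key_rejected(self, tmp_path):
        cfg_file = tmp_path / "cfg.yaml"
        cfg_file.write_text("definitely_not_a_key: 1\n")
        with pytest.raises(ConfigError):
            syn.config_from_yaml(cfg_file)
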