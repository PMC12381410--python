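"""Synthetic cohort generator: planted structure, determinism, moments."""
import numpy as np
import pytest

import mcqcpm as mc
from mcqcpm.connectome import POWER14_NETWORKS
from mcqcpm.errors import InvalidConfigError
from mcqcpm.synthetic import CohortConfig, LongitudinalSpec, MediationPathSpec

from conftest import covmat


class TestGenerateAtlas:
    def test_power_like_atlas_uses_canonical_networks(self):
        atlas = mc.generate_atlas(264, 14, seed=1)
        assert atlas.n_nodes == 264
        labels = set(atlas.labels)
        assert labels == set(POWER14_NETWORKS)
        assert {"DMN", "VAN", "VIS"} <= labels

    def test_one_node_per_network_when_counts_equal(self):
        atlas = mc.generate_atlas(3, 3, seed=99)
        assert len(set(atlas.labels)) == 3

    def test_seeded_determinism_byte_identical(self, tmp_path):
        a1 = mc.generate_atlas(10, 2, seed=7)
        a2 = mc.generate_atlas(10, 2, seed=7)
        p1, p2 = tmp_path / "a1.tsv", tmp_path / "a2.tsv"
        a1.to_tsv(p1)
        a2.to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_every_network_nonempty(self):
        atlas = mc.generate_atlas(30, 14, seed=0)
        assert len(set(atlas.labels)) == 14

    def test_too_many_networks_rejected(self):
        with pytest.raises(InvalidConfigError):
            mc.generate_atlas(5, 6, seed=0)


class TestConfigValidation:
    def test_overlapping_planted_sets_rejected(self):
        cfg = CohortConfig(
            planted_pos_edges={"CSC": [1, 2, 3]},
            planted_neg_edges={"NEG": [3, 4]},
        )
        with pytest.raises(InvalidConfigError, match="overlap"):
            cfg.validate()

    def test_out_of_range_edge_index_rejected(self):
        cfg = CohortConfig(n_nodes=10, n_networks=5, planted_pos_edges={"CSC": [45]})
        with pytest.raises(InvalidConfigError, match="out of range"):
            cfg.validate()

    def test_effect_r_bounds(self):
        with pytest.raises(InvalidConfigError):
            CohortConfig(effect_r=1.0).validate()
        CohortConfig(effect_r=0.0).validate()  # null cohort is allowed

    def test_tiny_cohort_rejected(self):
        with pytest.raises(InvalidConfigError):
            CohortConfig(n_subjects=5).validate()


class TestGenerateCohort:
    def test_bit_identical_under_same_seed(self):
        cfg = mc.default_planted_config(seed=5, n_subjects=40, n_nodes=15, n_planted=5)
        d1, d2 = mc.generate_cohort(cfg), mc.generate_cohort(cfg)
        np.testing.assert_array_equal(d1.edges.values, d2.edges.values)
        assert d1.behavior.equals(d2.behavior)
        assert d1.atlas.nodes.equals(d2.atlas.nodes)

    def test_planted_edges_hit_target_correlation(self, planted_cohort):
        """Sample r of planted edges with the behavior is 0.5 +/- 0.15 for
        at least 90% of the planted set."""
        d = planted_cohort
        y = d.behavior["CSC"].to_numpy()
        idx = d.ground_truth.planted_pos["CSC"]
        rs = np.array(
            [np.corrcoef(d.edges.values[:, i], y)[0, 1] for i in idx]
        )
        assert np.mean(np.abs(rs - 0.5) <= 0.15) >= 0.90

    def test_null_cohort_edges_independent_of_behavior(self):
        """With effect_r = 0, the selection hit rate matches the p threshold."""
        d = mc.generate_cohort(mc.null_config(seed=42))
        y = d.behavior["CSC"].to_numpy()
        sel = mc.select_edges(d.edges, y, covmat(d.behavior), 0.01)
        rate = (sel.n_pos + sel.n_neg) / d.edges.n_edges
        assert rate < 0.03  # ~binomial(1770, 0.01) upper band

    def test_covariate_moments_at_n1000(self):
        cfg = CohortConfig(n_subjects=1000, n_nodes=15, effect_r=0.0, seed=8)
        d = mc.generate_cohort(cfg)
        cm = cfg.covariate_model
        assert d.behavior["age"].mean() == pytest.approx(cm.age_mean, abs=3 * cm.age_sd / np.sqrt(1000))
        assert d.behavior["age"].std() == pytest.approx(cm.age_sd, rel=0.15)
        assert d.behavior["gender"].mean() == pytest.approx(cm.female_prop, abs=0.05)
        assert d.behavior["motion"].mean() == pytest.approx(cm.motion_mean, abs=0.01)

    def test_planted_mediation_indirect_effect_consistency(self):
        """Generated a=0.5, b=0.5, c'=0 gives empirical indirect ~ 0.25."""
        x, m, y = mc.simulate_mediation_triple(0.5, 0.5, 0.0, 20000, seed=3)
        a_hat = np.polyfit(x, m, 1)[0]
        b_hat = np.linalg.lstsq(np.column_stack([x, m, np.ones_like(x)]), y, rcond=None)[0][1]
        assert a_hat * b_hat == pytest.approx(0.25, abs=0.02)

    def test_time_series_mode_preserves_planted_structure(self):
        """FC computed from emitted time series shows the same planted-edge
        correlation structure (within sampling error) as direct FC."""
        cfg = mc.default_planted_config(
            seed=2, n_subjects=60, n_nodes=15, n_planted=8, n_timepoints_ts=400
        )
        d = mc.generate_cohort(cfg)
        assert d.edges is None and len(d.timeseries) == 60
        table = mc.edge_table_from_matrices([mc.compute_fc(ts) for ts in d.timeseries])
        y = d.behavior["CSC"].to_numpy()
        idx = d.ground_truth.planted_pos["CSC"]
        rs = np.array([np.corrcoef(table.values[:, i], y)[0, 1] for i in idx])
        assert rs.mean() == pytest.approx(0.5, abs=0.15)
        other = np.setdiff1d(np.arange(table.n_edges), idx)[:20]
        rs_null = np.array([np.corrcoef(table.values[:, i], y)[0, 1] for i in other])
        assert abs(rs_null.mean()) < 0.15

    def test_longitudinal_followup_structure(self):
        cfg = mc.default_planted_config(
            seed=6, longitudinal=LongitudinalSpec(change_coupling=0.4, driver="CSC")
        )
        d = mc.generate_cohort(cfg)
        followed = d.behavior["interval_days"].notna()
        assert followed.sum() == round(159 / 180 * 180)
        assert d.behavior.loc[followed, "interval_days"].between(365, 545).all()
        assert d.behavior.loc[~followed, "BAI_t2"].isna().all()
        # change scores correlate with the planted-network strength
        from mcqcpm.longitudinal import change_table

        ch = change_table(d.behavior, ("BAI",))
        s = d.ground_truth.driver_strength[followed.to_numpy()]
        r = np.corrcoef(s, ch["BAI_change"])[0, 1]
        assert r > 0.2

    def test_mediation_path_ties_behavior_latent_share(self):
        cfg = mc.default_planted_config(
            seed=9,
            n_subjects=2000,
            n_nodes=15,
            n_planted=5,
            mediation_paths=(MediationPathSpec("CSC", "BAI", a=0.6, b=0.5, c_prime=0.1),),
        )
        d = mc.generate_cohort(cfg)
        g = d.ground_truth.latents["CSC"]
        m = d.behavior["CSC"].to_numpy()
        assert np.corrcoef(g, m)[0, 1] == pytest.approx(0.6, abs=0.06)
        assert d.ground_truth.true_indirect["CSC->BAI"] == pytest.approx(0.3)


class TestWriters:
    def test_write_cohort_emits_all_files(self, tmp_path):
        cfg = mc.default_planted_config(seed=1, n_subjects=12, n_nodes=8, n_planted=3)
        data = mc.generate_cohort(cfg)
        mc.synthetic.write_cohort(data, tmp_path)
        for name in ("atlas.tsv", "behavior.csv", "edges.csv", "ground_truth.json"):
            assert (tmp_path / name).exists()
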