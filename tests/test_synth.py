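"""Generator correctness: determinism, planted structure, oracle distances."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.sparse.csgraph import floyd_warshall

import moascan as m
from moascan import preprocess as pp


def _clean_config(**kwargs):
    """Panel with every nuisance source switched off except what the test plants."""
    base = dict(
        n_cell_lines=120, n_genes=80, n_drugs=4,
        n_essential=15, n_nonessential=15,
        covariate_sd=0.0, latent_scale=0.0, biomarker_effect=0.0,
        missing_rate=0.0, seed=5,
    )
    base.update(kwargs)
    return m.PanelConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_cell_lines", 0),
            ("n_drugs", -2),
            ("missing_rate", 1.0),
            ("noise_sd", -0.1),
        ],
    )
    def test_invalid_fields_reported_by_name(self, field, value):
        with pytest.raises(ValueError, match=field):
            m.PanelConfig(**{field: value})

    def test_reference_sets_must_fit_in_gene_space(self):
        with pytest.raises(ValueError, match="n_essential"):
            m.PanelConfig(n_genes=10, n_essential=8, n_nonessential=8)


class TestDeterminism:
    def test_identical_seed_identical_outputs_across_generators(self):
        config = m.PanelConfig(
            n_cell_lines=40, n_genes=120, n_drugs=5,
            n_essential=15, n_nonessential=15, seed=7,
        )
        a, b = m.generate_panel(config), m.generate_panel(config)
        pd.testing.assert_frame_equal(a.fold_changes.values, b.fold_changes.values)
        pd.testing.assert_frame_equal(a.drug_response.values, b.drug_response.values)
        pd.testing.assert_frame_equal(a.cell_meta, b.cell_meta)
        assert a.truth.targets == b.truth.targets

        ga, ta = m.generate_ppi_network(config, a.truth)
        gb, tb = m.generate_ppi_network(config, b.truth)
        assert nx.utils.graphs_equal(ga, gb)
        pd.testing.assert_frame_equal(ta, tb)

        fa = m.generate_molecular_features(config, a.truth, a)
        fb = m.generate_molecular_features(config, b.truth, b)
        pd.testing.assert_frame_equal(fa[0], fb[0])
        pd.testing.assert_frame_equal(fa[1], fb[1])

        ra, tra = m.generate_bioactivity_table(config)
        rb, trb = m.generate_bioactivity_table(config)
        pd.testing.assert_frame_equal(ra, rb)
        assert tra["active_sets"] == trb["active_sets"]

    def test_different_seed_differs(self):
        a = m.generate_panel(_clean_config(seed=1))
        b = m.generate_panel(_clean_config(seed=2))
        assert not a.fold_changes.values.equals(b.fold_changes.values)


class TestPanelStructure:
    def test_masking_removes_exact_count(self):
        config = m.PanelConfig(
            n_cell_lines=50, n_genes=100, n_drugs=7,
            n_essential=10, n_nonessential=10, missing_rate=0.13, seed=3,
        )
        panel = m.generate_panel(config)
        expected = round(0.13 * 7 * 50)
        assert int(panel.drug_response.values.isna().sum().sum()) == expected

    def test_essential_baseline_below_nonessential(self, small_panel):
        raw = small_panel.fold_changes.values
        ess = raw.loc[small_panel.truth.essential].mean().mean()
        ne = raw.loc[small_panel.truth.nonessential].mean().mean()
        assert ess < -1.5 < ne

    def test_targets_present_in_fitness_matrix(self, small_panel):
        genes = set(small_panel.fold_changes.genes)
        assert set(small_panel.truth.targets.values()) <= genes

    def test_null_effect_gives_null_correlations(self):
        """With no planted effect and no confounders, drug-gene correlations
        sit inside the null sampling band."""
        panel = m.generate_panel(_clean_config(target_effect=0.0))
        sfm = pp.scale_fold_changes(panel.fold_changes, panel.gene_sets)
        n = panel.config.n_cell_lines
        rs = []
        for drug, target in panel.truth.targets.items():
            y = panel.drug_response.values.loc[drug]
            for gene in list(sfm.values.index[:10]) + [target]:
                rs.append(stats.pearsonr(y, sfm.values.loc[gene]).statistic)
        # under the null, |r| exceeds the 95% band about 5% of the time
        band = 1.96 / np.sqrt(n - 3)
        exceed = np.mean([abs(r) > band for r in rs])
        assert exceed < 0.20
        assert abs(np.mean(rs)) < 2 * band

    def test_attenuation_matches_closed_form_monte_carlo(self):
        """Mean drug-target correlation over replicate panels agrees with the
        closed-form attenuation r = b*sx / sqrt(b^2 sx^2 + sigma^2); with the
        planted signal variance matched to the noise variance, r ~ 1/sqrt(2)."""
        noise = 0.5
        pilot = m.generate_panel(_clean_config(target_effect=0.0, noise_sd=noise))
        sfm = pp.scale_fold_changes(pilot.fold_changes, pilot.gene_sets)
        sx = float(np.mean([
            sfm.values.loc[t].std() for t in pilot.truth.targets.values()
        ]))
        beta = noise / sx  # signal sd = noise sd

        measured, predicted = [], []
        for seed in range(50):
            panel = m.generate_panel(
                _clean_config(target_effect=beta, noise_sd=noise, seed=100 + seed)
            )
            sfm = pp.scale_fold_changes(panel.fold_changes, panel.gene_sets)
            for drug, target in panel.truth.targets.items():
                x = sfm.values.loc[target]
                y = panel.drug_response.values.loc[drug]
                measured.append(stats.pearsonr(y, x).statistic)
                sx_rep = x.std()
                predicted.append(
                    beta * sx_rep / np.sqrt(beta**2 * sx_rep**2 + noise**2)
                )
        assert np.mean(measured) == pytest.approx(np.mean(predicted), abs=0.03)
        assert np.mean(measured) == pytest.approx(1 / np.sqrt(2), abs=0.05)

    def test_shared_latent_loading_drives_profile_similarity(self):
        """Cell-line pairs with similar lineage loadings have more correlated
        fitness profiles (rank correlation over 100 pairs)."""
        panel = m.generate_panel(
            m.PanelConfig(n_cell_lines=60, n_genes=200, n_drugs=4,
                          n_essential=20, n_nonessential=20,
                          latent_scale=1.0, seed=9)
        )
        F = panel.fold_changes.values.to_numpy()
        L = panel.truth.latent_loadings.to_numpy()
        rng = np.random.default_rng(0)
        sims, cors = [], []
        for _ in range(100):
            i, j = rng.choice(60, size=2, replace=False)
            sims.append(L[i] @ L[j])
            cors.append(np.corrcoef(F[:, i], F[:, j])[0, 1])
        assert stats.spearmanr(sims, cors).statistic > 0


class TestPPIGenerator:
    def test_designated_distances_realized(self, small_config, small_panel):
        graph, table = m.generate_ppi_network(small_config, small_panel.truth)
        for target, gene, distance in table.itertuples(index=False):
            if distance < 0:
                assert not nx.has_path(graph, target, gene)
            else:
                assert nx.shortest_path_length(graph, target, gene) == distance

    def test_decoy_component_unreachable(self, small_config, small_panel):
        graph, table = m.generate_ppi_network(small_config, small_panel.truth)
        decoys = set(table.loc[table["distance"] < 0, "gene"])
        assert decoys
        targets = set(small_panel.truth.targets.values())
        for d in decoys:
            for t in targets:
                assert not nx.has_path(graph, t, d)

    def test_distances_match_floyd_warshall_oracle(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(30, 0.15, seed=11)
        dense = floyd_warshall(nx.to_numpy_array(g, nodelist=range(30), weight=None))
        for source, lengths in nx.all_pairs_shortest_path_length(g):
            for node in range(30):
                if node in lengths:
                    assert lengths[node] == int(dense[source, node])
                else:
                    assert np.isinf(dense[source, node])

    def test_unrealizable_distances_reported(self):
        config = m.PanelConfig(
            n_cell_lines=10, n_genes=12, n_drugs=8,
            n_essential=1, n_nonessential=1, seed=2,
        )
        panel = m.generate_panel(config)
        with pytest.raises(ValueError, match="free genes"):
            m.generate_ppi_network(config, panel.truth)


class TestMolecularFeatures:
    def test_genomic_matrix_strictly_binary(self, small_config, small_panel):
        genomic, _ = m.generate_molecular_features(
            small_config, small_panel.truth, small_panel
        )
        assert set(np.unique(genomic.to_numpy())) <= {0, 1}

    def test_noiseless_planted_feature_shifts_response_exactly(self):
        config = _clean_config(
            noise_sd=0.0, target_effect=0.0, biomarker_effect=2.0, seed=13
        )
        panel = m.generate_panel(config)
        bm = panel.truth.biomarkers
        genomic_row = bm[bm["feature_class"] == "genomic"].iloc[0]
        vec = panel.truth.biomarker_values[genomic_row["feature_id"]]
        y = panel.drug_response.values.loc[genomic_row["drug_id"]].to_numpy()
        diff = y[vec == 0].mean() - y[vec == 1].mean()  # altered lines sensitized
        assert diff == pytest.approx(2.0, abs=1e-10)

    def test_decoy_features_independent_of_outcomes(self):
        panel = m.generate_panel(_clean_config(seed=17))
        genomic, expression = m.generate_molecular_features(
            panel.config, panel.truth, panel
        )
        drug = panel.drug_response.drugs[0]
        y = panel.drug_response.values.loc[drug].to_numpy()
        rs = [
            stats.pearsonr(expression.loc[f], y).statistic
            for f in expression.index if f.startswith("gexp_decoy")
        ]
        assert abs(np.mean(rs)) < 2 / np.sqrt(panel.config.n_cell_lines)


class TestBioactivityGenerator:
    def test_absent_pchembl_flagged_ineligible(self):
        records, truth = m.generate_bioactivity_table(m.PanelConfig(seed=31))
        eligible = truth["record_eligible"]
        assert (~eligible[records["pchembl"].isna()]).all()

    def test_kinase_at_ten_nanomolar_active(self):
        records, truth = m.generate_bioactivity_table(m.PanelConfig(seed=31))
        strong_kinase = records[
            truth["record_eligible"]
            & (records["family"] == "Kinase")
            & (records["pchembl"] >= 8.0)
        ]
        assert not strong_kinase.empty
        for _, rec in strong_kinase.iterrows():
            assert rec["target_id"] in truth["active_sets"][rec["drug_id"]]


class TestWriters:
    def test_roundtrip_through_pipeline_readers(self, tmp_path, small_panel):
        from moascan import pipeline

        paths = m.write_panel(small_panel, tmp_path)
        fc = pipeline.load_fitness_matrix(paths["fitness"])
        pd.testing.assert_frame_equal(
            fc.values, small_panel.fold_changes.values, check_names=False
        )
        drm = pipeline.load_drug_response(paths["drug_response"], paths["drug_meta"])
        pd.testing.assert_frame_equal(
            drm.values, small_panel.drug_response.values, check_names=False
        )
        assert drm.targets == small_panel.drug_response.targets
        ess = pipeline.load_gene_list(paths["essential"])
        assert set(ess) == set(small_panel.truth.essential)
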