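"""Generator contracts: determinism, planted structure, and the variance law."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from sigrepo.connectivity import connectivity_score
from sigrepo.simulate import (
    SimulationConfig,
    gen_dose_response,
    gen_expression_cohort,
    gen_gene_sets,
    gen_microscopy_image,
    gen_proteomic_panel,
    gen_signature_library,
    gen_compound_knowledgebase,
    four_pl,
    planted_signature,
)


class TestExpressionCohort:
    def test_null_effect_plants_nothing(self):
        cfg = SimulationConfig(effect_log2fc=0.0, n_planted_pathways=0, seed=3)
        _, truth = gen_expression_cohort(cfg)
        assert truth.planted_genes == {}

    def test_zero_effect_size_records_zero_effects(self):
        cfg = SimulationConfig(effect_log2fc=0.0, seed=3)
        _, truth = gen_expression_cohort(cfg)
        assert all(e == 0.0 for e in truth.planted_genes.values())

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=11)
        a, ta = gen_expression_cohort(cfg)
        b, tb = gen_expression_cohort(cfg)
        pd.testing.assert_frame_equal(a.values, b.values)
        assert ta.planted_genes == tb.planted_genes

    def test_variance_law_matches_scaled_inverse_chisquare(self):
        # var(log s2_true) should equal trigamma(d0/2) under the prior
        cfg = SimulationConfig(n_genes=5000, variance_prior=(4.0, 2.0), seed=5)
        _, truth = gen_expression_cohort(cfg)
        v = np.array(list(truth.true_variances.values()))
        observed = np.var(np.log(v), ddof=1)
        expected = special.polygamma(1, 2.0)  # trigamma(d0/2), d0=4
        assert observed == pytest.approx(expected, rel=0.10)

    def test_group_size_below_two_rejected(self):
        with pytest.raises(ValueError, match="group"):
            gen_expression_cohort(SimulationConfig(group_sizes=(1, 5, 5)))

    def test_status_counts_match_config(self):
        cfg = SimulationConfig(group_sizes=(4, 6, 5), seed=0)
        ds, _ = gen_expression_cohort(cfg)
        counts = ds.status.value_counts()
        assert (counts["Healthy"], counts["NAFL"], counts["NASH"]) == (4, 6, 5)


class TestGeneSets:
    def test_no_planted_pathways(self):
        col = gen_gene_sets(SimulationConfig(n_planted_pathways=0, seed=1))
        assert not [n for n in col if n.startswith("PLANTED")]

    def test_planted_pathway_count_is_eleven_by_default(self, universe):
        planted = [n for n in universe["collection"] if n.startswith("PLANTED")]
        assert len(planted) == 11
        assert universe["truth"].planted_pathways == sorted(planted)

    def test_every_planted_gene_in_a_planted_pathway(self, universe):
        covered = set()
        for name in universe["truth"].planted_pathways:
            covered.update(universe["collection"].members(name))
        assert set(universe["truth"].planted_genes) <= covered

    def test_infeasible_set_sizes_rejected(self):
        with pytest.raises(ValueError, match="set_size_range"):
            gen_gene_sets(SimulationConfig(n_genes=20, set_size_range=(10, 40)))

    def test_no_empty_sets(self, universe):
        assert all(len(universe["collection"].members(n)) > 0
                   for n in universe["collection"])


class TestSignatureLibrary:
    def test_noiseless_reverser_scores_strongly_negative(self, universe):
        sig = planted_signature(universe["truth"])
        profile = universe["library"]["REV_00"]
        _, _, score = connectivity_score(profile, sig)
        # maximum attainable |score| for tags of size t in universe n is
        # 1 - (t-1)/(2n) per tag; a noiseless reverser should be within 5%
        assert score < -0.9

    def test_mimicker_scores_strongly_positive(self, universe):
        sig = planted_signature(universe["truth"])
        _, _, score = connectivity_score(universe["library"]["MIM_00"], sig)
        assert score > 0.9

    def test_decoy_connectivity_centred_on_zero(self):
        # Monte-Carlo mean over many decoys (fresh universes) is ~0
        scores = []
        for seed in range(100):
            cfg = SimulationConfig(n_genes=200, n_library_compounds=1, n_reversers=0,
                                   n_mimickers=0, tag_size=10, seed=seed)
            _, truth = gen_expression_cohort(cfg)
            lib = gen_signature_library(truth, cfg)
            sig = planted_signature(truth)
            _, _, s = connectivity_score(lib["DEC_000"], sig)
            scores.append(s)
        assert abs(np.mean(scores)) < 0.05

    def test_too_many_actives_rejected(self):
        cfg = SimulationConfig(n_library_compounds=5, n_reversers=3, n_mimickers=3)
        with pytest.raises(ValueError, match="exceeds"):
            cfg.validate()

    def test_empty_library_is_valid(self):
        cfg = SimulationConfig(n_library_compounds=0, n_reversers=0, n_mimickers=0, seed=1)
        _, truth = gen_expression_cohort(cfg)
        lib = gen_signature_library(truth, cfg)
        assert len(lib) == 0


class TestCompoundKB:
    @pytest.mark.parametrize("fraction,expected", [(0.0, 0), (1.0, 110)])
    def test_tox_fraction_extremes(self, fraction, expected):
        cfg = SimulationConfig(tox_fraction=fraction, seed=9)
        _, truth = gen_expression_cohort(cfg)
        col = gen_gene_sets(cfg)
        gen_signature_library(truth, cfg)
        kb = gen_compound_knowledgebase(truth, cfg, col)
        assert sum(kb.tox.values()) == expected

    def test_actives_target_planted_pathways(self, universe):
        col, kb = universe["collection"], universe["kb"]
        planted = set(universe["truth"].planted_pathways)
        for c, role in universe["truth"].compound_roles.items():
            if role in ("reverser", "mimicker"):
                assert col.sets_containing(kb.targets[c]) & planted

    def test_mimickers_jointly_cover_all_planted_pathways(self, universe):
        col, kb = universe["collection"], universe["kb"]
        covered = set()
        for c, role in universe["truth"].compound_roles.items():
            if role == "mimicker":
                covered |= col.sets_containing(kb.targets[c])
        assert set(universe["truth"].planted_pathways) <= covered


class TestMicroscopyImage:
    def test_truth_records_planted_counts(self):
        ch, truth = gen_microscopy_image(SimulationConfig(seed=0))
        assert len(truth.nuclei_centers) == 12
        assert len(truth.droplets) == 40
        assert ch["nuclei"].shape == ch["droplets"].shape == (512, 512)

    def test_blank_config_gives_background_only(self):
        cfg = SimulationConfig(n_nuclei=0, n_droplets=0, seed=0)
        ch, truth = gen_microscopy_image(cfg)
        assert np.allclose(ch["nuclei"], cfg.background)
        assert np.allclose(ch["droplets"], cfg.background)
        assert truth.nuclei_centers == [] and truth.droplets == []

    def test_touching_pair_overlaps_exactly_once(self):
        cfg = SimulationConfig(seed=4, touching_pair=True)
        _, truth = gen_microscopy_image(cfg)
        c = np.array(truth.nuclei_centers)
        d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        overlapping_pairs = int((d < 2 * cfg.nucleus_radius).sum()) // 2
        assert overlapping_pairs == 1

    def test_infeasible_placement_raises(self):
        cfg = SimulationConfig(image_width=64, image_height=64, n_nuclei=50, seed=0)
        with pytest.raises(RuntimeError, match="place"):
            gen_microscopy_image(cfg)


class TestDoseResponseGenerator:
    def test_noise_free_on_curve(self):
        params = {"top": 100.0, "bottom": 0.0, "c50": 10.0, "slope": 1.0}
        doses = np.geomspace(0.1, 100, 6)
        plate = gen_dose_response(params, doses, noise_sd=0.0, seed=0)
        assert np.allclose(plate["value"], four_pl(doses, 100, 0, 10, 1))

    def test_flat_truth_when_slope_zero(self):
        params = {"top": 100.0, "bottom": 0.0, "c50": 10.0, "slope": 0.0}
        plate = gen_dose_response(params, np.geomspace(0.1, 100, 6), seed=0)
        assert np.ptp(plate["value"]) == 0

    def test_reproducible_and_needs_five_doses(self):
        params = {"top": 100.0, "bottom": 0.0, "c50": 10.0, "slope": 1.0}
        a = gen_dose_response(params, [1, 2, 4, 8, 16], noise_sd=2.0, seed=7)
        b = gen_dose_response(params, [1, 2, 4, 8, 16], noise_sd=2.0, seed=7)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError, match="5 dose"):
            gen_dose_response(params, [1, 2, 4], seed=0)


class TestProteomicPanel:
    def test_separated_centroids_and_reproducibility(self):
        X1, y1 = gen_proteomic_panel(separation=10.0, seed=1)
        X2, _ = gen_proteomic_panel(separation=10.0, seed=1)
        pd.testing.assert_frame_equal(X1, X2)
        assert sorted(set(y1)) == [0, 1, 2, 3]

    def test_single_centroid(self):
        _, y = gen_proteomic_panel(n_clusters=1, seed=0)
        assert set(y) == {0}
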