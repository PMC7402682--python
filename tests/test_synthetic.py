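"""Generator properties: determinism, null behaviour, truth recovery,
nesting structure, and the publication-bias selection mechanism."""

import math

import numpy as np
import pandas as pd
import pytest

import befmeta as b
from conftest import null_truth


class TestConfigValidation:
    def test_bad_probabilities(self):
        with pytest.raises(ValueError, match="probabilities"):
            b.TruthConfig(moderator_probs={
                "study_type": {"experimental": 0.7, "observational": 0.7},
                "taxon_group": {"animal": 0.7, "microbe": 0.3},
                "diversity_metric": {"richness": 0.7, "diversity_index": 0.3},
            })

    def test_bad_ranges(self):
        with pytest.raises(ValueError):
            b.TruthConfig(dup_range=(0, 3))
        with pytest.raises(ValueError):
            b.TruthConfig(n_obs_range=(3, 30))
        with pytest.raises(ValueError):
            b.TruthConfig(obs_per_study_range=(10, 4))

    def test_negative_sd(self):
        with pytest.raises(ValueError):
            b.TruthConfig(tau_study=-0.1)


class TestEffectTable:
    def test_seed_determinism(self, default_truth):
        a = b.generate_effect_table(default_truth).effects
        c = b.generate_effect_table(default_truth).effects
        pd.testing.assert_frame_equal(a, c)

    def test_paper_scale_defaults(self, effects_dataset):
        eff = effects_dataset.effects
        bio = eff[eff["response"] != "decomposition"]
        assert eff["case_study_id"].nunique() == 69
        assert 450 <= len(bio) <= 900  # ~660 biodiversity/abundance observations
        assert set(eff["driver"]) == {"stressor", "nutrient"}

    def test_linkage_invariant(self, effects_dataset):
        eff = effects_dataset.effects
        dec_links = set(eff.loc[eff["response"] == "decomposition", "link_key"])
        bio_links = set(eff.loc[eff["response"] != "decomposition", "link_key"])
        assert dec_links <= bio_links

    def test_null_model_mean_near_zero(self):
        cfg = null_truth(n_studies=60, obs_per_study_range=(8, 9), seed=21)
        eff = b.generate_effect_table(cfg).effects
        bio = eff[eff["response"] != "decomposition"]
        se = np.sqrt(bio["var_z"].mean() / len(bio))
        assert abs(bio["z"].mean()) < 3 * se

    def test_ols_recovers_decomposition_path(self):
        # regression of observed z_LD on the true biodiversity effect; the
        # independent oracle for the structural coefficient is plain OLS
        cfg = null_truth(n_studies=250, obs_per_study_range=(2, 3), path_b=0.5,
                         tau_study=0.2, sigma_obs=0.2, dup_range=(1, 1), seed=33)
        ds = b.generate_effect_table(cfg)
        eff = ds.effects
        dec = eff[eff["response"] == "decomposition"].set_index("link_key")
        bio = eff[eff["response"] != "decomposition"].set_index("link_key")
        true_b = bio["true_z"].reindex(dec.index)
        slope = np.polyfit(true_b, dec["z"], 1)[0]
        n = len(dec)
        mc_se = np.std(dec["z"]) / (np.std(true_b) * math.sqrt(n))
        assert slope == pytest.approx(0.5, abs=3 * mc_se)

    def test_sampling_variance_matches_reported(self):
        # observed z scatter around the true effect ~ mean 1/(n-3)
        cfg = null_truth(n_studies=1000, obs_per_study_range=(10, 10),
                         dup_range=(1, 1), dup_jitter_sd=0.0, seed=44)
        eff = b.generate_effect_table(cfg).effects
        bio = eff[eff["response"] != "decomposition"]
        resid = bio["z"] - bio["true_z"]
        ratio = resid.var() / bio["var_z"].mean()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_nesting_icc_grows_with_tau(self):
        def icc(tau):
            cfg = null_truth(n_studies=150, obs_per_study_range=(6, 6),
                             tau_study=tau, sigma_obs=0.2, seed=55)
            eff = b.generate_effect_table(cfg).effects
            bio = eff[eff["response"] != "decomposition"]
            grand = bio["true_z"].var()
            within = bio.groupby("case_study_id")["true_z"].var().mean()
            return 1.0 - within / grand

        assert icc(0.05) < icc(0.3) < icc(0.8)


class TestRawStudies:
    def test_seed_determinism(self):
        cfg = b.TruthConfig(n_studies=8, seed=2)
        a = b.generate_raw_studies(cfg).observations
        c = b.generate_raw_studies(cfg).observations
        assert len(a) == len(c)
        assert all(x == y for x, y in zip(a, c))

    def test_null_records_recover_zero_on_average(self):
        zs = []
        for r in range(40):
            cfg = null_truth(n_studies=5, obs_per_study_range=(1, 2),
                             design_mix=1.0, missing_sd_rate=0.0, seed=600 + r)
            res = b.build_effect_table(b.generate_raw_studies(cfg).observations)
            zs.extend(e.z for e in res.effects)
        se = np.std(zs) / math.sqrt(len(zs))
        assert abs(np.mean(zs)) < 3 * se

    def test_collinear_gradient_recovers_r_one(self):
        levels = [b.GradientLevel(1.0 + 2 * i, 2.0 + i) for i in range(5)]
        rec = b.ObservationRecord(
            obs_id="g", case_study_id="s", publication_id="p", driver="nutrient",
            design="gradient", response="abundance", link_key="l", levels=levels,
        )
        (e,) = b.build_effect_table([rec]).effects
        assert e.z == pytest.approx(math.atanh(0.999))  # clipped perfect correlation

    def test_target_r_recovered_through_chain(self):
        # control-treatment records implying r=0.5 at n=50/group: mean recovered
        # z over replicates within Monte-Carlo error of atanh(0.5)=0.5493
        zs = []
        for r in range(60):
            cfg = null_truth(
                n_studies=8, obs_per_study_range=(1, 1), design_mix=1.0,
                missing_sd_rate=0.0, dup_range=(1, 1),
                mu_abundance={"stressor": 0.5493, "nutrient": 0.5493},
                mu_diversity={"stressor": 0.5493, "nutrient": 0.5493},
                response_mix=0.0, n_obs_range=(50, 50), seed=700 + r,
            )
            res = b.build_effect_table(b.generate_raw_studies(cfg).observations)
            zs.extend(e.z for e in res.effects if e.response == "abundance")
        mc_se = np.std(zs) / math.sqrt(len(zs))
        assert np.mean(zs) == pytest.approx(0.5493, abs=3 * mc_se)

    def test_missing_sds_present_and_flagged(self, raw_dataset):
        res = b.build_effect_table(raw_dataset.observations)
        assert any(e.sd_approximated for e in res.effects)

    def test_compound_intensity_round_trips(self, raw_dataset):
        # the strongest compound's standardized level reproduces the latent
        # intensity that generated the record
        rec = next(r for r in raw_dataset.observations if r.compound_levels)
        val, comp = b.max_intensity(rec.compound_levels)
        assert -2.5 < val < 3.5


class TestPublicationBias:
    def test_strength_zero_is_identity(self, effects_dataset):
        out = b.apply_publication_bias(effects_dataset, 0.0, seed=1)
        pd.testing.assert_frame_equal(out.effects, effects_dataset.effects)

    def test_subset_property_and_determinism(self, effects_dataset):
        out1 = b.apply_publication_bias(effects_dataset, 2.0, seed=5)
        out2 = b.apply_publication_bias(effects_dataset, 2.0, seed=5)
        assert len(out1.effects) <= len(effects_dataset.effects)
        pd.testing.assert_frame_equal(out1.effects, out2.effects)

    def test_selection_favours_significant_positives(self, effects_dataset):
        out = b.apply_publication_bias(effects_dataset, 4.0, seed=3)
        t_all = effects_dataset.effects["z"] / np.sqrt(effects_dataset.effects["var_z"])
        t_kept = out.effects["z"] / np.sqrt(out.effects["var_z"])
        assert t_kept.mean() > t_all.mean()

    def test_linkage_preserved_after_selection(self, effects_dataset):
        out = b.apply_publication_bias(effects_dataset, 4.0, seed=3)
        eff = out.effects
        dec_links = set(eff.loc[eff["response"] == "decomposition", "link_key"])
        bio_links = set(eff.loc[eff["response"] != "decomposition", "link_key"])
        assert dec_links <= bio_links

    def test_negative_strength_rejected(self, effects_dataset):
        with pytest.raises(ValueError):
            b.apply_publication_bias(effects_dataset, -1.0, seed=0)
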