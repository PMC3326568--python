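import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from tilsig.simulate import (
    SimulationConfig,
    generate_cohort,
    generate_expression,
    generate_ihc,
    generate_latent_classes,
    generate_outcomes,
    generate_survival,
)
from tilsig.stats import ContingencyTable2x2, fisher_exact_two_sided
from tilsig.survival import logrank_test


def _cfg(**kw):
    return SimulationConfig(**kw)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"class_proportions": (0.5, 0.5, 0.1)},
            {"class_proportions": (1.2, -0.1, -0.1)},
            {"noise_sd": 0.0},
            {"baseline_hazard": -1.0},
            {"within_block_rho": 1.0},
            {"n_noise_probes": -1},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            _cfg(**kw)

    def test_yaml_round_trip(self, tmp_path):
        cfg = _cfg(seed=9, n_cases=42)
        cfg.to_file(tmp_path / "c.yaml")
        back = SimulationConfig.from_file(tmp_path / "c.yaml")
        assert back == cfg


class TestExpression:
    def test_same_seed_bit_identical(self):
        m1, l1 = generate_expression(_cfg(seed=5, n_cases=40))
        m2, l2 = generate_expression(_cfg(seed=5, n_cases=40))
        assert l1 == l2
        pd.testing.assert_frame_equal(m1.data, m2.data)

    def test_different_seed_differs(self):
        m1, _ = generate_expression(_cfg(seed=5, n_cases=40))
        m2, _ = generate_expression(_cfg(seed=6, n_cases=40))
        assert not m1.data.equals(m2.data)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="6 cases"):
            generate_expression(_cfg(n_cases=5))

    def test_zero_noise_limit_separates_three_value_groups(self):
        cfg = _cfg(seed=2, n_cases=60, noise_sd=1e-9, class_means=(1.0, 0.0, -1.0))
        matrix, latent = generate_expression(cfg)
        row = pd.Series(matrix.row("CD3D"), index=matrix.sample_ids)
        for cls, mean in zip(("high", "intermediate", "low"), (1.0, 0.0, -1.0)):
            members = [s for s, c in latent.items() if c == cls]
            np.testing.assert_allclose(row[members], mean, atol=1e-6)

    def test_anchor_correlation_exceeds_block_threshold(self):
        # Monte-Carlo check of the shared-factor construction, 10 seeds.
        for seed in range(1, 11):
            matrix, _ = generate_expression(_cfg(seed=seed, n_cases=300))
            rho = spearmanr(matrix.row("CD3D"), matrix.row("CD247")).statistic
            assert rho > 0.7, f"seed {seed}: rho {rho:.3f}"

    def test_matrix_contains_signature_anchors_and_noise(self):
        cfg = _cfg(seed=1, n_cases=20, n_noise_probes=7)
        matrix, _ = generate_expression(cfg)
        for gene in cfg.signature_genes + cfg.anchor_genes:
            assert gene in matrix.row_ids
        assert sum(r.startswith("NOISE") for r in matrix.row_ids) == 7


class TestOutcomes:
    def test_saturating_effect_gives_pcr_to_every_high_case(self):
        cfg = _cfg(seed=3, n_cases=200, pcr_logit_intercept=-20.0, pcr_logit_effect=40.0)
        latent = generate_latent_classes(cfg)
        outcomes = generate_outcomes(latent, cfg)
        for s, cls in latent.items():
            assert outcomes[s] == ("pCR" if cls == "high" else "RD")

    def test_rates_match_logistic_link(self):
        # intercept/effect defaults encode response probabilities 0.31 / 0.74
        cfg = _cfg(seed=4, n_cases=5000)
        latent = generate_latent_classes(cfg)
        outcomes = generate_outcomes(latent, cfg)
        high = [s for s, c in latent.items() if c == "high"]
        rest = [s for s, c in latent.items() if c != "high"]
        rate_high = np.mean([outcomes[s] == "pCR" for s in high])
        rate_rest = np.mean([outcomes[s] == "pCR" for s in rest])
        assert abs(rate_high - 0.74) < 0.02
        assert abs(rate_rest - 0.31) < 0.02

    def test_null_effect_is_calibrated(self):
        # with no planted effect the class/outcome Fisher test should be null
        hits = 0
        for seed in range(100):
            cfg = _cfg(seed=seed, n_cases=200, pcr_logit_effect=0.0)
            latent = generate_latent_classes(cfg)
            outcomes = generate_outcomes(latent, cfg)
            frame = pd.DataFrame(
                {"cls": pd.Series(latent), "out": pd.Series(outcomes)}
            )
            a = int(((frame.cls == "high") & (frame.out == "pCR")).sum())
            b = int(((frame.cls == "high") & (frame.out == "RD")).sum())
            c = int(((frame.cls != "high") & (frame.out == "pCR")).sum())
            d = int(((frame.cls != "high") & (frame.out == "RD")).sum())
            p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
            hits += p > 0.01
        assert hits >= 95

    def test_empty_latent_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_outcomes({}, _cfg())


class TestSurvival:
    @staticmethod
    def _flat_hr_config(seed, n):
        hr = {(t, c): 1.0 for t in ("none", "anthracycline")
              for c in ("high", "intermediate", "low")}
        return _cfg(seed=seed, n_cases=n, treatment_hr_by_class=hr)

    def test_null_logrank_chi_square_has_unit_mean(self):
        chis = []
        for seed in range(200):
            cfg = self._flat_hr_config(seed, 80)
            latent = generate_latent_classes(cfg)
            rng = np.random.default_rng(seed)
            treat = {s: ("anthracycline" if rng.random() < 0.5 else "none")
                     for s in latent}
            frame = generate_survival(latent, treat, cfg)
            chis.append(
                logrank_test(frame, groups=("anthracycline", "none")).chi_square
            )
        assert 0.8 < np.mean(chis) < 1.25

    def test_zero_hazard_multiplier_means_zero_events(self):
        cfg = _cfg(
            seed=1,
            n_cases=100,
            treatment_hr_by_class={
                (t, c): (0.0 if t == "anthracycline" else 1.0)
                for t in ("none", "anthracycline")
                for c in ("high", "intermediate", "low")
            },
        )
        latent = generate_latent_classes(cfg)
        treat = {s: ("anthracycline" if i % 2 else "none")
                 for i, s in enumerate(latent)}
        frame = generate_survival(latent, treat, cfg)
        assert frame.loc[frame.group == "anthracycline", "event"].sum() == 0

    def test_hazard_ratio_recovery(self):
        # planted HR 0.28 recovered by the Mantel-Haenszel estimate
        ok = 0
        for seed in range(50):
            cfg = _cfg(seed=seed, n_cases=800)
            latent = {f"S{i}": "high" for i in range(800)}
            treat = {s: ("anthracycline" if i < 400 else "none")
                     for i, s in enumerate(latent)}
            frame = generate_survival(latent, treat, cfg)
            hr = logrank_test(frame, groups=("anthracycline", "none")).hazard_ratio
            ok += 0.2 <= hr <= 0.4
        assert ok >= 45

    def test_unknown_treatment_rejected(self):
        cfg = _cfg(seed=1, n_cases=10)
        latent = generate_latent_classes(cfg)
        treat = {s: "radiotherapy" for s in latent}
        with pytest.raises(ValueError, match="radiotherapy"):
            generate_survival(latent, treat, cfg)


class TestIHC:
    def test_near_zero_intensity_gives_zero_counts(self):
        cfg = _cfg(seed=1, n_cases=50, ihc_mean_by_class=(1e-9, 1e-9, 1e-9))
        cores = generate_ihc(generate_latent_classes(cfg), cfg)
        assert all(c.raw_count == 0 for c in cores)

    def test_same_seed_identical_draws(self):
        cfg = _cfg(seed=8, n_cases=30)
        latent = generate_latent_classes(cfg)
        c1 = generate_ihc(latent, cfg)
        c2 = generate_ihc(latent, cfg)
        assert c1 == c2

    def test_high_low_density_contrast_recovered(self):
        # planted 7.8-fold intensity contrast shows up in normalized densities
        cfg = _cfg(seed=5, n_cases=1000)
        latent = generate_latent_classes(cfg)
        cores = generate_ihc(latent, cfg)
        dens = pd.DataFrame(
            {
                "sample": [c.sample_id for c in cores],
                "density": [c.raw_count / c.epithelial_fraction for c in cores],
            }
        )
        dens["cls"] = dens["sample"].map(latent)
        ratio = (
            dens.loc[dens.cls == "high", "density"].mean()
            / dens.loc[dens.cls == "low", "density"].mean()
        )
        assert 6 <= ratio <= 10

    def test_two_cores_per_case(self):
        cfg = _cfg(seed=1, n_cases=25)
        cores = generate_ihc(generate_latent_classes(cfg), cfg)
        counts = pd.Series([c.sample_id for c in cores]).value_counts()
        assert (counts == 2).all()


class TestCohort:
    def test_ids_consistent_across_components(self, default_cohort):
        ids = set(default_cohort.expression.sample_ids)
        assert ids == set(default_cohort.clinical["sample_id"])
        assert ids == set(default_cohort.latent_class)
        assert ids == {c.sample_id for c in default_cohort.ihc}

    def test_adjuvant_setting_has_survival_and_arms(self):
        cohort = generate_cohort(_cfg(seed=2, n_cases=80), setting="adjuvant")
        assert cohort.clinical["dfs_months"].notna().all()
        assert set(cohort.clinical["treatment"]) <= {"none", "CMF", "anthracycline"}

    def test_neoadjuvant_setting_uses_trial_arms(self, default_cohort):
        assert set(default_cohort.clinical["treatment"]) <= {"FEC", "TET"}

    def test_unknown_setting_rejected(self):
        with pytest.raises(ValueError, match="setting"):
            generate_cohort(_cfg(), setting="metastatic")

    def test_response_score_tracks_outcome(self, default_cohort):
        clin = default_cohort.clinical
        good = clin["response_score"] >= 3
        assert (good == (clin["outcome"] == "pCR")).all()
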