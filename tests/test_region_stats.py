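"""Region mean extraction, the mixed model, and effect contrasts."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from srica import (effect_contrasts, extract_region_means, fit_lmm,
                   marginal_mean_rows)
from srica.synthetic import HEMI_CODE_OFFSET


def simulated_sample(rng, n_participants=20, regions=(1, 2, 3, 4), fc_maps=(0, 1),
                     participant_sd=0.5, noise_sd=0.3, region_effects=None,
                     interaction=None, hemi_effect=0.0):
    """Balanced RegionSample with known generative parameters."""
    rows = []
    region_effects = region_effects or {r: 0.0 for r in regions}
    interaction = interaction or {}
    for p in range(n_participants):
        u = rng.normal(0, participant_sd)
        for h, hval in (("L", hemi_effect / 2), ("R", -hemi_effect / 2)):
            for f in fc_maps:
                for r in regions:
                    mu = u + hval + region_effects[r] + interaction.get((f, r), 0.0)
                    rows.append((f"sub-{p:03d}", h, r, f, mu + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows, columns=["participant_id", "hemisphere", "region",
                                       "fc_map", "mean_z"])


class TestExtractRegionMeans:
    def test_constant_region_returns_constant(self, grid, anatomy):
        V = int(anatomy.brain_mask.sum())
        vox = grid.flat_indices(anatomy.brain_mask)
        maps = np.zeros((1, V))
        lab_flat = anatomy.atlas.ravel()[vox]
        maps[0, (lab_flat % HEMI_CODE_OFFSET) == 3] = 2.5
        df = extract_region_means({"p": maps}, {"p": anatomy.atlas}, grid, vox)
        got = df[(df.region == 3)]
        assert np.allclose(got.mean_z, 2.5)

    def test_matches_voxel_loop_oracle_with_jittered_atlases(self, grid, tiny_cohort):
        vox = grid.flat_indices(tiny_cohort.template.brain_mask)
        rng = np.random.default_rng(0)
        maps = {pid: rng.standard_normal((2, len(vox)))
                for pid in tiny_cohort.participant_ids}
        atlases = {pid: an.atlas for pid, an in
                   tiny_cohort.participant_anatomy.items()}
        df = extract_region_means(maps, atlases, grid, vox)
        flat_atlas = {pid: a.ravel()[vox] for pid, a in atlases.items()}
        for _, row in df.sample(60, random_state=1).iterrows():
            lab = flat_atlas[row.participant_id]
            code = row.region + (HEMI_CODE_OFFSET if row.hemisphere == "R" else 0)
            expect = np.mean([maps[row.participant_id][row.fc_map, i]
                              for i in range(len(vox)) if lab[i] == code])
            assert row.mean_z == pytest.approx(expect, abs=1e-10)

    def test_absent_region_warns_and_omits_row(self, grid, anatomy):
        vox = grid.flat_indices(anatomy.brain_mask)
        maps = {"a": np.zeros((1, len(vox))), "b": np.zeros((1, len(vox)))}
        atlas_b = anatomy.atlas.copy()
        atlas_b[atlas_b == 5] = 6  # drop left region 5 for participant b
        with pytest.warns(UserWarning, match="empty"):
            df = extract_region_means({"a": maps["a"], "b": maps["b"]},
                                      {"a": anatomy.atlas, "b": atlas_b}, grid, vox)
        assert len(df[(df.participant_id == "b") & (df.region == 5) &
                      (df.hemisphere == "L")]) == 0
        assert len(df[(df.participant_id == "a") & (df.region == 5) &
                      (df.hemisphere == "L")]) == 1


class TestFitLmm:
    def test_recovers_participant_variance(self, rng):
        df = simulated_sample(rng, participant_sd=0.5,
                              region_effects={1: 0.0, 2: 1.0, 3: 0.0, 4: 1.0})
        fit = fit_lmm(df)
        assert fit.random_intercept and not fit.singular
        assert fit.participant_var == pytest.approx(0.25, rel=0.5)

    def test_all_identical_gives_null_model(self):
        rows = [(f"s{p}", h, r, f, 1.0)
                for p in range(5) for h in "LR" for r in (1, 2, 3) for f in (0, 1)]
        df = pd.DataFrame(rows, columns=["participant_id", "hemisphere",
                                         "region", "fc_map", "mean_z"])
        with pytest.warns(UserWarning, match="singular"):
            fit = fit_lmm(df)
        assert fit.singular
        con = effect_contrasts(fit)
        np.testing.assert_allclose(con.estimate, 0.0, atol=1e-10)
        assert np.all(fit.anova.chi2 < 1e-8)

    def test_interaction_power_at_large_effect(self, rng):
        """One region elevated in one FC map only (effect 1.0, noise 0.3):
        the interaction is detected essentially always."""
        hits = 0
        n_sim = 25
        for _ in range(n_sim):
            df = simulated_sample(rng, n_participants=20, noise_sd=0.3,
                                  interaction={(0, 2): 1.0})
            fit = fit_lmm(df)
            hits += fit.interaction_p < 0.05
        assert hits >= 0.95 * n_sim

    def test_ols_limit_matches_closed_form(self, rng):
        """Without the random intercept, fixed effects equal plain OLS and
        marginal means equal raw cell means on a balanced design."""
        df = simulated_sample(rng, participant_sd=0.0,
                              region_effects={1: 0.2, 2: -0.4, 3: 0.0, 4: 0.7},
                              interaction={(1, 4): 0.5})
        fit = fit_lmm(df, include_random=False)
        mm = marginal_mean_rows(fit)
        for (f, r), row in mm.items():
            cell = df[(df.fc_map == f) & (df.region == r)]["mean_z"].mean()
            assert row @ fit.params == pytest.approx(cell, abs=1e-8)

    def test_hemisphere_main_effect_detected(self, rng):
        df = simulated_sample(rng, hemi_effect=0.3)
        fit = fit_lmm(df)
        row = fit.anova[fit.anova.term.str.contains("hemisphere")]
        assert float(row["p"].iloc[0]) < 1e-6

    def test_needs_enough_levels(self, rng):
        df = simulated_sample(rng)
        with pytest.raises(ValueError, match="hemisphere"):
            fit_lmm(df[df.hemisphere == "L"])


class TestEffectContrasts:
    def test_known_cell_means(self, rng):
        """Region means {2, 0, 0} give mean-of-others contrasts {2, -1, -1}."""
        df = simulated_sample(rng, regions=(1, 2, 3), fc_maps=(0,),
                              participant_sd=0.0, noise_sd=1e-6,
                              region_effects={1: 2.0, 2: 0.0, 3: 0.0})
        fit = fit_lmm(df, include_random=False)
        con = effect_contrasts(fit)
        np.testing.assert_allclose(con.estimate, [2.0, -1.0, -1.0], atol=1e-4)
        assert con.estimate.sum() == pytest.approx(0.0, abs=1e-10)

    def test_grand_mean_variant_is_scaled(self, rng):
        df = simulated_sample(rng, region_effects={1: 1.0, 2: 0.0, 3: -0.5, 4: 0.2})
        fit = fit_lmm(df)
        a = effect_contrasts(fit, variant="mean_of_others")
        b = effect_contrasts(fit, variant="grand_mean")
        R = 4
        np.testing.assert_allclose(a.estimate, b.estimate * R / (R - 1), atol=1e-10)
        pd.testing.assert_series_equal(a.z_ratio, b.z_ratio, atol=1e-8)

    def test_bonferroni_bounds(self, rng):
        df = simulated_sample(rng, region_effects={1: 0.5, 2: 0.0, 3: 0.0, 4: 0.1})
        con = effect_contrasts(fit_lmm(df))
        assert np.all(con.p_adj >= con.p_raw - 1e-15)
        assert np.all(con.p_adj <= 1.0)
        assert np.all((con.z_ratio * con.se - con.estimate).abs() < 1e-10)

    def test_embedded_parcels_rank_top(self, rng):
        """Regions with a planted elevation in one FC map rank top by
        z-ratio for that map, mirroring how network membership is read off
        a contrast table."""
        df = simulated_sample(rng, interaction={(0, 2): 1.0, (0, 3): 0.8},
                              noise_sd=0.3)
        con = effect_contrasts(fit_lmm(df))
        top = con[con.fc_map == 0].sort_values("z_ratio", ascending=False)
        assert set(top.region.iloc[:2]) == {2, 3}


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestAgainstLme4:
    def test_fixed_effects_match_lmer(self, tmp_path, rng):
        """Independent oracle: lme4/lmerTest REML on the same balanced data
        reproduces our fixed effects and contrast scale."""
        df = simulated_sample(rng, n_participants=8, regions=(1, 2, 3),
                              participant_sd=0.4, noise_sd=0.3,
                              interaction={(0, 2): 0.6})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f"""
            suppressMessages({{library(lme4); library(emmeans)}})
            d <- read.csv("{csv}")
            d$hemisphere <- factor(d$hemisphere); d$region <- factor(d$region)
            d$fc_map <- factor(d$fc_map)
            m <- lmer(mean_z ~ hemisphere + fc_map * region + (1 | participant_id),
                      data = d, REML = TRUE)
            em <- as.data.frame(emmeans(m, ~ region | fc_map))
            vc <- as.data.frame(VarCorr(m))
            cat(jsonlite::toJSON(list(emm = em$emmean, vc = vc$vcov), digits = 12))
        """)
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        ref = json.loads(out.stdout)
        fit = fit_lmm(df)
        mm = marginal_mean_rows(fit)
        ours = [float(mm[(f, r)] @ fit.params)
                for f in fit.fc_maps for r in fit.regions]
        # emmeans orders region within fc_map
        np.testing.assert_allclose(sorted(ours), sorted(ref["emm"]), atol=1e-5)
        assert fit.participant_var == pytest.approx(ref["vc"][0], abs=1e-5)
        assert fit.resid_var == pytest.approx(ref["vc"][1], abs=1e-5)
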