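"""Synthetic cohort generator: determinism, calibration, planted structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from checkupnet import (
    SyntheticConfig,
    generate_cross_sectional,
    generate_longitudinal,
    quantify_weekly_alcohol,
    truth_table,
)
from checkupnet.questionnaire import encode_table
from checkupnet.synthetic import (
    build_alcohol_ladder,
    build_model,
    delta_alcohol_moments,
    resolved_attenuation_beta,
)


class TestDeterminism:
    def test_identical_config_reproduces_tables_exactly(self):
        cfg = SyntheticConfig(n=300, seed=12345)
        t1, _ = generate_cross_sectional(cfg)
        t2, _ = generate_cross_sectional(cfg)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_longitudinal_reproducible(self):
        cfg = SyntheticConfig(n=200, seed=7)
        p1, g1 = generate_longitudinal(cfg)
        p2, g2 = generate_longitudinal(cfg)
        pd.testing.assert_frame_equal(p1.followup.data, p2.followup.data)
        assert g1.attenuation_beta == g2.attenuation_beta

    def test_different_seed_differs(self):
        t1, _ = generate_cross_sectional(SyntheticConfig(n=100, seed=0))
        t2, _ = generate_cross_sectional(SyntheticConfig(n=100, seed=1))
        assert not t1.data["FVC"].equals(t2.data["FVC"])


class TestCrossSectionalCalibration:
    def test_drinking_mix_matches_study_population(self):
        cfg = SyntheticConfig(n=6036, seed=20)
        table, _ = generate_cross_sectional(cfg)
        mix = table.data["drinking_category"].value_counts(normalize=True)
        for category, target in zip(
            ("never", "light", "moderate", "heavy"), (0.264, 0.285, 0.360, 0.087)
        ):
            assert mix.get(category, 0.0) == pytest.approx(target, abs=0.02)

    def test_demographic_moments(self):
        cfg = SyntheticConfig(n=6036, seed=21)
        table, _ = generate_cross_sectional(cfg)
        assert table.data["age"].mean() == pytest.approx(60.0, abs=0.6)
        assert table.data["age"].std() == pytest.approx(13.0, abs=0.5)
        assert (table.data["sex"] == "male").mean() == pytest.approx(0.612, abs=0.02)
        assert table.data["FVC"].mean() == pytest.approx(3.60, abs=0.05)

    def test_planted_edges_calibrated_at_large_n(self):
        cfg = SyntheticConfig(n=20000, seed=22)
        table, truth = generate_cross_sectional(cfg)
        r = encode_table(table).corr()
        for v1, v2, target in truth.edges:
            assert r.loc[v1, v2] == pytest.approx(target, abs=0.02), (v1, v2)

    def test_confounder_geometry_induces_product_correlation(self):
        cfg = SyntheticConfig.gaussian(
            ["x", "y", "z"],
            confounders=[("z", "x", "y", 0.5, 0.5)],
            n=20000,
            seed=23,
        )
        table, truth = generate_cross_sectional(cfg)
        r = table.data.corr()
        assert truth.confounded_pairs == (("x", "y", 0.25, "z"),)
        assert r.loc["x", "z"] == pytest.approx(0.5, abs=0.02)
        assert r.loc["y", "z"] == pytest.approx(0.5, abs=0.02)
        assert r.loc["x", "y"] == pytest.approx(0.25, abs=0.02)
        # no direct dependence: partialling out z leaves nothing
        partial = (r.loc["x", "y"] - r.loc["x", "z"] * r.loc["y", "z"]) / np.sqrt(
            (1 - r.loc["x", "z"] ** 2) * (1 - r.loc["y", "z"] ** 2)
        )
        assert partial == pytest.approx(0.0, abs=0.03)

    def test_empty_structure_gives_independent_variables(self):
        cfg = SyntheticConfig.gaussian([f"v{i}" for i in range(6)], n=6036, seed=24)
        table, _ = generate_cross_sectional(cfg)
        r = table.data.corr().to_numpy()
        off = r[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_infeasible_structure_fails_before_sampling(self):
        cfg = SyntheticConfig.gaussian(
            ["a", "b", "c"],
            planted_edges=[("a", "b", 0.9), ("a", "c", 0.9), ("b", "c", -0.9)],
            n=100,
            seed=0,
        )
        with pytest.raises(ValueError, match="positive definite"):
            generate_cross_sectional(cfg)

    def test_latent_matrix_checked_for_feasible_targets(self):
        cfg = SyntheticConfig(n=100, seed=0)
        model = build_model(cfg)  # raises if the default structure is inconsistent
        assert model.chol.shape[0] == len(model.latent_names)

    def test_answer_labels_consistent_with_weekly_grams(self):
        table, _ = generate_cross_sectional(SyntheticConfig(n=200, seed=25))
        for _, row in table.data.iterrows():
            g = quantify_weekly_alcohol(
                row["alcohol_volume_level"], row["alcohol_frequency_level"]
            )
            assert g == pytest.approx(row["alcohol_weekly_g"])


class TestAlcoholLadder:
    def test_probabilities_sum_to_one(self):
        cfg = SyntheticConfig(n=100, seed=0)
        ladder = build_alcohol_ladder(cfg.quantification, cfg.drinking_mix)
        assert sum(ladder.probs) == pytest.approx(1.0)

    def test_rungs_sorted_by_grams_and_categories_contiguous(self):
        cfg = SyntheticConfig(n=100, seed=0)
        ladder = build_alcohol_ladder(cfg.quantification, cfg.drinking_mix)
        grams = np.asarray(ladder.grams)
        assert (np.diff(grams) >= 0).all()
        assert ladder.categories[0] == "never"

    def test_attenuation_coefficient_matches_simulation(self):
        cfg = SyntheticConfig(n=100, seed=0)
        ladder = build_alcohol_ladder(cfg.quantification, cfg.drinking_mix)
        rng = np.random.default_rng(0)
        z = rng.standard_normal(400_000)
        g = np.asarray(ladder.grams)[ladder.step.interval_index(z)]
        assert np.corrcoef(g, z)[0, 1] == pytest.approx(
            ladder.step.attenuation(), abs=0.005
        )


class TestLongitudinal:
    def test_mean_fvc_decline_and_zero_change_fraction(self):
        cfg = SyntheticConfig(n=1765, seed=30)
        paired, truth = generate_longitudinal(cfg)
        d_fvc = paired.followup.data["FVC"] - paired.baseline.data["FVC"]
        d_alc = (
            paired.followup.data["alcohol_weekly_g"]
            - paired.baseline.data["alcohol_weekly_g"]
        )
        assert d_fvc.mean() == pytest.approx(-0.10, abs=0.02)
        assert (d_alc == 0).mean() == pytest.approx(0.533, abs=0.03)
        assert truth.zero_change_fraction == pytest.approx(0.533)

    def test_null_attenuation_leaves_deltas_uncorrelated(self):
        # average the delta-correlation over replicates: its population value is 0
        vals = []
        for rep in range(10):
            cfg = SyntheticConfig(n=1765, seed=3000 + rep, attenuation_beta=0.0)
            paired, _ = generate_longitudinal(cfg)
            d_fvc = paired.followup.data["FVC"] - paired.baseline.data["FVC"]
            d_alc = (
                paired.followup.data["alcohol_weekly_g"]
                - paired.baseline.data["alcohol_weekly_g"]
            )
            vals.append(np.corrcoef(d_alc, d_fvc)[0, 1])
        assert abs(np.mean(vals)) < 0.025

    def test_default_beta_targets_the_requested_delta_correlation(self):
        cfg = SyntheticConfig(n=1765, seed=31)
        beta = resolved_attenuation_beta(cfg)
        _, sd = delta_alcohol_moments(cfg)
        sd_noise = cfg.followup_noise_sd["FVC"]
        implied = beta * sd / 100 / np.hypot(beta * sd / 100, sd_noise)
        assert implied == pytest.approx(cfg.target_delta_correlation, abs=1e-9)

    def test_age_advances_five_years_and_smoking_is_stable(self):
        paired, _ = generate_longitudinal(SyntheticConfig(n=100, seed=32))
        np.testing.assert_allclose(
            paired.followup.data["age"] - paired.baseline.data["age"], 5.0
        )
        assert (
            paired.followup.data["smoking_status"]
            == paired.baseline.data["smoking_status"]
        ).all()

    def test_category_change_bookkeeping_matches_tables(self):
        paired, truth = generate_longitudinal(SyntheticConfig(n=800, seed=33))
        changed = (
            paired.followup.data["drinking_category"]
            != paired.baseline.data["drinking_category"]
        ).mean()
        assert truth.category_change_fraction == pytest.approx(changed)


class TestTruthTable:
    def test_row_per_planted_parameter(self):
        cfg = SyntheticConfig(n=1765, seed=34)
        _, truth = generate_longitudinal(cfg)
        tt = truth_table(truth)
        assert (tt["kind"] == "direct").sum() == len(truth.edges)
        assert (tt["kind"] == "indirect").sum() == len(truth.confounded_pairs)
        assert "attenuation_beta" in set(tt["kind"])

    def test_indirect_rows_name_their_source(self):
        _, truth = generate_cross_sectional(SyntheticConfig(n=100, seed=35))
        tt = truth_table(truth)
        indirect = tt[tt["kind"] == "indirect"]
        assert (indirect["source"] != "").all()

    def test_round_trip_through_tsv(self, tmp_path):
        _, truth = generate_cross_sectional(SyntheticConfig(n=100, seed=36))
        tt = truth_table(truth)
        path = tmp_path / "truth.tsv"
        tt.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t", keep_default_na=False)
        assert len(back) == len(tt)
        pd.testing.assert_series_equal(
            back["value"].astype(float), tt["value"].astype(float), check_names=False
        )


def test_config_validation():
    with pytest.raises(ValueError, match="n must be"):
        SyntheticConfig(n=5)
    with pytest.raises(ValueError, match="mixture"):
        SyntheticConfig(drinking_mix=(0.5, 0.5, -0.1, 0.1))
    with pytest.raises(ValueError, match="extra_variables"):
        build_model(dataclasses.replace(SyntheticConfig(), include_checkup=False))
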