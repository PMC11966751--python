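import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magflux import synthdata as sd
from magflux.iodata import ConfigError, reference_plant
from magflux.massbalance import (
    MassBalanceError,
    classify_dominance,
    compute_net_growth,
    compute_srt,
    daily_load_ratio,
    run_mass_balance,
    run_mass_balance_by_class,
    summarize_immigration,
)


class TestScalarBalances:
    def test_equal_proportions_give_system_srt(self, plant):
        # proportions cancel: theta = M_AGS/(J_ES + J_EF) = 55972/3433
        assert compute_srt(0.02, 0.02, 0.02, plant) == pytest.approx(16.304, abs=5e-4)

    def test_srt_hand_example(self, plant):
        # 0.05*55972 / (0.02*2177 + 0.001*1256) = 2798.6/44.796
        assert compute_srt(0.05, 0.02, 0.001, plant) == pytest.approx(62.47, abs=5e-3)

    def test_srt_infinite_when_nothing_leaves(self, plant):
        assert math.isinf(compute_srt(0.05, 0.0, 0.0, plant))

    def test_srt_requires_reactor_presence(self, plant):
        with pytest.raises(MassBalanceError):
            compute_srt(0.0, 0.01, 0.01, plant)

    def test_mu_equals_inverse_srt_without_immigration(self, plant):
        mu = compute_net_growth(0.03, 0.01, 0.004, 0.0, plant)
        theta = compute_srt(0.03, 0.01, 0.004, plant)
        assert mu == pytest.approx(1.0 / theta)
        assert mu > 0

    def test_mu_zero_at_exact_balance(self, plant):
        p_ww = 0.01 * (plant.j_es + plant.j_ef) / plant.j_ww
        assert compute_net_growth(0.01, 0.01, 0.01, p_ww, plant) == pytest.approx(0.0, abs=1e-15)

    def test_mu_hand_example(self, plant):
        # (34.33 - 412.25)/559.72 = -0.6752 per day
        mu = compute_net_growth(0.01, 0.01, 0.01, 0.10, plant)
        assert mu == pytest.approx(-0.6752, abs=5e-5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=st.tuples(*[st.floats(0.001, 0.5) for _ in range(4)]),
        c=st.floats(0.01, 100),
    )
    def test_mu_scale_invariance(self, p, c):
        """Multiplying all compartment fractions of a MAG by c leaves mu unchanged."""
        plant = reference_plant()
        p_ags, p_es, p_ef, p_ww = p
        mu1 = compute_net_growth(p_ags, p_es, p_ef, p_ww, plant)
        mu2 = compute_net_growth(c * p_ags, c * p_es, c * p_ef, c * p_ww, plant)
        assert mu2 == pytest.approx(mu1, rel=1e-9, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p_es=st.floats(0.001, 0.2),
        p_ef=st.floats(0.001, 0.2),
        shrink=st.floats(0.1, 0.9),
    )
    def test_theta_increases_as_wastage_decreases(self, p_es, p_ef, shrink):
        plant = reference_plant()
        base = compute_srt(0.05, p_es, p_ef, plant)
        assert compute_srt(0.05, p_es * shrink, p_ef, plant) > base
        assert compute_srt(0.05, p_es, p_ef * shrink, plant) > base

    def test_daily_load_ratio_reference_plant(self, plant):
        ratio = daily_load_ratio(plant)
        assert ratio == pytest.approx(100 * 4122.5 / 55972)
        assert round(ratio / 0.5) * 0.5 == 7.5

    def test_daily_load_ratio_proportionality(self, plant):
        assert daily_load_ratio(plant.with_j_ww(plant.m_ags)) == pytest.approx(100.0)
        assert daily_load_ratio(plant.with_j_ww(0.1 * plant.m_ags)) == pytest.approx(10.0)


class TestRunMassBalance:
    def test_resident_only_mag_grows_at_inverse_srt(self, balanced_profiles, plant):
        rec = run_mass_balance(balanced_profiles, plant).set_index("mag_id")
        row = rec.loc["MAG_002"]  # absent from influent, present in reactor
        assert row["flags"] == "resident_only"
        assert row["growth_class"] == "positive"
        assert row["mu_per_day"] == pytest.approx(1.0 / row["theta_days"])

    def test_washed_out_mag_kept_with_undefined_class(self, balanced_profiles, plant):
        rec = run_mass_balance(balanced_profiles, plant).set_index("mag_id")
        row = rec.loc["MAG_003"]  # influent only
        assert row["flags"] == "washed_out"
        assert row["growth_class"] == "undefined"
        assert math.isnan(row["mu_per_day"])

    def test_missing_compartment_raises(self, make_profiles, plant):
        pm = make_profiles({"influent.rep1": [0.1], "AGS.mixed.rep1": [0.1]})
        with pytest.raises(ConfigError, match="excess_sludge"):
            run_mass_balance(pm, plant)

    def test_transcriptomic_phases_are_averaged(self, make_profiles, plant):
        pm = make_profiles(
            {
                "influent.rep1": [0.01],
                "excess_sludge.rep1": [0.03],
                "effluent.rep1": [0.03],
                "AGS.mixed.aerobic.rep1": [0.02],
                "AGS.mixed.anaerobic.rep1": [0.04],
            },
            kind="metatranscriptomics",
        )
        rec = run_mass_balance(pm, plant).set_index("mag_id")
        # p_AGS must be the phase mean 0.03
        assert rec.loc["MAG_001", "p_ags"] == pytest.approx(0.03)

    def test_noise_free_synthetic_recovery(self):
        """Whole-system mass balance recovers the generator's exact truth."""
        cfg = sd.three_guild_config(seed=11)
        truth = sd.generate_truth(cfg)
        ds = sd.emit_profiles(truth, cfg)
        rec = run_mass_balance(ds.dna, truth.plant)
        merged = rec.merge(
            truth.table[["mu_true", "theta_true"]], left_on="mag_id", right_index=True
        )
        assert np.abs(merged["mu_per_day"] - merged["mu_true"]).max() < 1e-9
        rel = np.abs(merged["theta_days"] - merged["theta_true"]) / merged["theta_true"]
        assert rel.max() < 1e-9

    def test_mixed_reconstruction_matches_class_sum(self, plant):
        cfg = sd.three_guild_config(seed=3)
        truth = sd.generate_truth(cfg)
        ds = sd.emit_profiles(truth, cfg)
        from magflux.massbalance import ags_mixed_vector

        mixed = ags_mixed_vector(ds.dna, 1, truth.plant)
        f = truth.plant.mlss_fractions
        by_hand = sum(
            f[cls] * ds.dna.select(compartment="AGS", aggregate_class=cls, replicate=1).iloc[:, 0]
            for cls in ("FL", "SG", "LG")
        )
        np.testing.assert_allclose(mixed, by_hand, atol=1e-15)


class TestPerClassBalance:
    def test_identical_classes_and_splits_give_identical_mu(self, make_profiles):
        plant = reference_plant()
        # force equal class composition everywhere so symmetry holds
        plant = plant.__class__(
            m_ags=plant.m_ags,
            j_es=plant.j_es,
            j_ef=plant.j_ef,
            j_ww=plant.j_ww,
            mlss_fractions={"FL": 1 / 3, "SG": 1 / 3, "LG": 1 / 3},
            es_fractions={"FL": 1 / 3, "SG": 1 / 3, "LG": 1 / 3},
            ef_fractions={"FL": 1 / 3, "SG": 1 / 3, "LG": 1 / 3},
        )
        pm = make_profiles(
            {
                "influent.rep1": [0.05],
                "excess_sludge.rep1": [0.02],
                "effluent.rep1": [0.02],
                "AGS.FL.rep1": [0.02],
                "AGS.SG.rep1": [0.02],
                "AGS.LG.rep1": [0.02],
            }
        )
        rec = run_mass_balance_by_class(pm, plant, influent_split="mlss")
        mus = rec.set_index("scope")["mu_per_day"]
        assert mus["FL"] == pytest.approx(mus["SG"]) == pytest.approx(mus["LG"])

    def test_effluent_defaults_to_flocs_only(self, make_profiles, plant):
        pm = make_profiles(
            {
                "influent.rep1": [0.0],
                "excess_sludge.rep1": [0.0],
                "effluent.rep1": [0.5],
                "AGS.FL.rep1": [0.02],
                "AGS.SG.rep1": [0.02],
                "AGS.LG.rep1": [0.02],
            }
        )
        rec = run_mass_balance_by_class(pm, plant).set_index("scope")
        # SG and LG see no effluent loss: infinite SRT; FL loses biomass
        assert math.isinf(rec.loc["SG", "theta_days"])
        assert math.isinf(rec.loc["LG", "theta_days"])
        assert np.isfinite(rec.loc["FL", "theta_days"])

    def test_class_equations_match_hand_computation(self, make_profiles, plant):
        pm = make_profiles(
            {
                "influent.rep1": [0.06],
                "excess_sludge.rep1": [0.03],
                "effluent.rep1": [0.01],
                "AGS.FL.rep1": [0.02],
                "AGS.SG.rep1": [0.04],
                "AGS.LG.rep1": [0.05],
            }
        )
        rec = run_mass_balance_by_class(pm, plant, influent_split="mlss").set_index("scope")
        f, g, h = plant.mlss_fractions, plant.es_fractions, plant.ef_fractions
        for cls, p_cls in (("FL", 0.02), ("SG", 0.04), ("LG", 0.05)):
            leaving = 0.03 * g[cls] * plant.j_es + 0.01 * h[cls] * plant.j_ef
            entering = 0.06 * f[cls] * plant.j_ww
            mu = (leaving - entering) / (p_cls * f[cls] * plant.m_ags)
            theta = p_cls * f[cls] * plant.m_ags / leaving
            assert rec.loc[cls, "mu_per_day"] == pytest.approx(mu)
            assert rec.loc[cls, "theta_days"] == pytest.approx(theta)

    @pytest.mark.parametrize("split", ["mlss", "all-to-FL", "uniform"])
    def test_influent_split_modes_run(self, split, plant):
        cfg = sd.three_guild_config(seed=5)
        truth = sd.generate_truth(cfg)
        ds = sd.emit_profiles(truth, cfg)
        rec = run_mass_balance_by_class(ds.dna, truth.plant, influent_split=split)
        assert set(rec["scope"]) == {"FL", "SG", "LG"}


class TestDominance:
    @pytest.mark.parametrize(
        "p, label",
        [(0.001, "dominant"), (0.00099, "rare"), (0.05, "dominant"), (0.0, "rare")],
    )
    def test_threshold_boundary_inclusive(self, make_profiles, plant, p, label):
        pm = make_profiles({"AGS.mixed.rep1": [p]})
        assert classify_dominance(pm, plant=plant).iloc[0] == label

    def test_enumerated_community(self, make_profiles, plant):
        pm = make_profiles({"AGS.mixed.rep1": [0.05, 0.002, 0.001, 0.0005, 0.0]})
        labels = classify_dominance(pm, plant=plant)
        assert (labels == "dominant").sum() == 3


class TestImmigrationSummary:
    def _records(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "mag_id",
                "replicate",
                "scope",
                "theta_days",
                "mu_per_day",
                "growth_class",
                "dominance",
                "flags",
                "p_ags",
                "p_ww",
            ],
        )

    def test_all_positive_means_zero_immigration(self):
        rec = self._records(
            [
                ("a", 1, "whole", 10, 0.01, "positive", "dominant", "", 0.1, 0.01),
                ("b", 1, "whole", 10, 0.02, "positive", "rare", "", 0.0005, 0.01),
            ]
        )
        s = summarize_immigration(rec)["whole"]
        assert s.immigration_rate_pct == 0.0

    def test_toy_cumulative_shares(self):
        rec = self._records(
            [
                ("a", 1, "whole", 10, -0.1, "negative", "rare", "", 0.02, 0.20),
                ("b", 1, "whole", 10, -0.2, "negative", "rare", "", 0.01, 0.25),
            ]
        )
        s = summarize_immigration(rec)["whole"]
        assert s.table.loc["negative", "ags_pct_mean"] == pytest.approx(3.0)
        assert s.table.loc["negative", "influent_pct_mean"] == pytest.approx(45.0)

    def test_replicate_mean_and_sample_sd(self):
        rows = []
        for rep, share in ((1, 0.03), (2, 0.04), (3, 0.05)):
            rows.append(("a", rep, "whole", 10, -0.1, "negative", "rare", "", share, 0.2))
        s = summarize_immigration(self._records(rows))["whole"]
        assert s.immigration_rate_pct == pytest.approx(4.0)
        assert s.immigration_rate_sd_pct == pytest.approx(1.0)

    def test_resident_only_mags_are_excluded(self):
        rec = self._records(
            [
                ("a", 1, "whole", 10, 0.05, "positive", "dominant", "resident_only", 0.3, 0.0),
                ("b", 1, "whole", 10, 0.01, "positive", "rare", "", 0.001, 0.01),
            ]
        )
        s = summarize_immigration(rec)["whole"]
        assert s.table.loc["positive", "n_mean"] == 1.0
        assert s.table.loc["positive", "ags_pct_mean"] == pytest.approx(0.1)
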