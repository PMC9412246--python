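"""Growth, mortality, survival and the stochastic productivity simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reefprod as rp
from reefprod.productivity import canonicalize, family_rows, group_rows

# frozen oracle values, computed independently with 30-digit arithmetic
W_002_29_137 = 39.5839965791748682917736487608
L1_VBGF_YEAR = 6.96734670143683288198100232504
M_10_20_05 = 1.58969995938745633073830277021
P_M365 = 0.99004983374916805357390597718
DW_COMPOSED = 0.00514049996585051803194486749819


class TestWeightFromLength:
    def test_cube_law_arithmetic(self):
        assert rp.weight_from_length(20.0, 0.01, 3.0) == pytest.approx(80.0, rel=1e-12)

    def test_high_precision_oracle(self):
        assert rp.weight_from_length(13.7, 0.02, 2.9) == pytest.approx(
            W_002_29_137, rel=1e-12
        )

    def test_vanishes_at_zero_length(self):
        assert rp.weight_from_length(1e-9, 0.01, 3.0) < 1e-20

    def test_strictly_increasing(self):
        L = np.linspace(0.5, 30, 100)
        w = rp.weight_from_length(L, 0.02, 2.9)
        assert (np.diff(w) > 0).all()

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            rp.weight_from_length(-1.0, 0.01, 3.0)


class TestVBGF:
    def test_age_closed_form(self):
        # L = Lmax (1 - e^-1) at Kmax = 1 is exactly one year old
        lmax = 25.0
        assert rp.age_at_length(lmax * (1 - np.exp(-1)), lmax, 1.0) == pytest.approx(
            1.0, rel=1e-12
        )

    def test_age_vanishes_at_zero_length(self):
        assert rp.age_at_length(1e-9, 10.0, 0.5) < 1e-8

    @settings(deadline=None, max_examples=50)
    @given(
        frac=st.floats(0.01, 0.95),
        lmax=st.floats(5.0, 100.0),
        kmax=st.floats(0.05, 3.0),
    )
    def test_length_age_round_trip(self, frac, lmax, kmax):
        L = lmax * frac
        t = rp.age_at_length(L, lmax, kmax)
        back = lmax * (1 - np.exp(-kmax * t))
        assert back == pytest.approx(L, rel=1e-9)

    def test_zero_dt_is_identity(self):
        assert rp.length_after(5.0, 10.0, 0.5, 0.0) == pytest.approx(5.0, rel=1e-12)

    def test_one_year_closed_form(self):
        assert rp.length_after(5.0, 10.0, 0.5, 365.0) == pytest.approx(
            L1_VBGF_YEAR, rel=1e-12
        )

    def test_growth_monotone_in_dt_and_bounded(self):
        dts = np.array([0.0, 1.0, 30.0, 365.0, 3650.0])
        L = np.array([rp.length_after(5.0, 10.0, 0.5, dt) for dt in dts])
        assert (np.diff(L) > 0).all() and (L < 10.0).all() and L[0] >= 5.0

    def test_near_asymptote_growth_vanishes(self):
        with pytest.warns(UserWarning, match="clamped"):
            L1 = rp.length_after(10.0, 10.0, 0.5, 1.0)
        assert L1 - 10.0 * (1 - 1e-3) < 1e-4


class TestDailyGrowthMass:
    def test_composed_oracle(self):
        assert rp.daily_growth_mass(5.0, 0.01, 3.0, 10.0, 0.5) == pytest.approx(
            DW_COMPOSED, rel=1e-10
        )

    def test_definitional_consistency(self):
        L1 = rp.length_after(5.0, 10.0, 0.5, 1.0)
        expected = rp.weight_from_length(L1, 0.01, 3.0) - rp.weight_from_length(
            5.0, 0.01, 3.0
        )
        assert rp.daily_growth_mass(5.0, 0.01, 3.0, 10.0, 0.5) == pytest.approx(
            expected, rel=1e-12
        )

    def test_negligible_at_asymptote(self):
        with pytest.warns(UserWarning):
            dw = rp.daily_growth_mass(10.0, 0.01, 3.0, 10.0, 0.5)
        # clamped just below Lmax: one-day gain is a vanishing fraction of W
        assert dw < 1e-4 * rp.weight_from_length(10.0, 0.01, 3.0)


class TestMortalityAndSurvival:
    def test_length_based_model_oracle(self):
        assert rp.natural_mortality(10.0, 20.0, 0.5) == pytest.approx(
            M_10_20_05, rel=1e-12
        )

    def test_decreasing_in_length(self):
        assert rp.natural_mortality(20.0, 40.0, 0.5) < rp.natural_mortality(
            10.0, 40.0, 0.5
        )

    def test_override_passthrough(self):
        m = rp.natural_mortality(10.0, 20.0, 0.5, m_override=1.23)
        assert m == pytest.approx(1.23, rel=1e-12)

    def test_nan_override_falls_back_to_model(self):
        m = rp.natural_mortality(10.0, 20.0, 0.5, m_override=np.nan)
        assert m == pytest.approx(M_10_20_05, rel=1e-12)

    def test_survival_zero_mortality(self):
        assert rp.daily_survival(0.0) == 1.0

    def test_survival_arithmetic(self):
        assert rp.daily_survival(3.65) == pytest.approx(P_M365, rel=1e-12)

    def test_survival_decreasing_in_m(self):
        m = np.linspace(0, 10, 50)
        assert (np.diff(rp.daily_survival(m)) < 0).all()

    def test_negative_mortality_rejected(self):
        with pytest.raises(ValueError):
            rp.daily_survival(-0.1)


def _make_assemblage(n_species, n_individuals, seed):
    rng = np.random.default_rng(seed)
    lmax = rng.uniform(8, 50, n_species)
    rows = []
    for i in range(n_species):
        n = n_individuals // n_species
        lengths = np.round(lmax[i] * rng.uniform(0.2, 0.8, n), 1)
        binned = pd.Series(lengths).value_counts()
        for length, cnt in binned.items():
            rows.append(
                {"survey_id": "sv", "species_id": f"sp{i}", "family": f"fam{i % 3}",
                 "diel_group": "diurnal" if i % 2 else "nocturnal",
                 "length_cm": float(length), "count": int(cnt),
                 "lw_a": 0.01 + 0.01 * rng.uniform(), "lw_b": 3.0,
                 "l_max_cm": float(lmax[i]),
                 "k_max_per_yr": float(rng.uniform(0.2, 2.0))}
            )
    return pd.DataFrame(rows)


class TestSimulateProductivity:
    def test_deterministic_limit_all_survive(self, toy_enriched):
        df = toy_enriched.assign(m_per_yr=1e-12)
        est = rp.simulate_productivity(df, n_iter=50, seed=1)
        assert est.sd_g == pytest.approx(0.0, abs=1e-9)
        assert est.mean_g == pytest.approx(est.expected_g, rel=1e-9)

    def test_all_dead_gives_zero(self, toy_enriched):
        df = toy_enriched.assign(m_per_yr=1e12)
        est = rp.simulate_productivity(df, n_iter=20, seed=1)
        assert est.mean_g == 0.0 and est.expected_g == pytest.approx(0.0, abs=1e-12)

    def test_empty_survey_is_zero_not_error(self, toy_enriched):
        est = rp.simulate_productivity(toy_enriched.iloc[:0], n_iter=10, seed=1)
        assert est.mean_g == 0.0 and est.sd_g == 0.0

    def test_monte_carlo_matches_closed_form(self):
        df = _make_assemblage(10, 500, seed=3)
        est = rp.simulate_productivity(df, n_iter=1000, seed=9)
        se = est.sd_g / np.sqrt(est.n_iter)
        assert abs(est.mean_g - est.expected_g) < 4 * se

    def test_brute_force_bernoulli_oracle(self):
        """Independent re-simulation: per-individual Bernoulli fates drawn
        with a different RNG must agree with the binomial implementation."""
        df = _make_assemblage(6, 200, seed=4)
        from reefprod.productivity import individual_energetics

        e = individual_energetics(canonicalize(df))
        rng = np.random.RandomState(12345)  # legacy Mersenne Twister
        totals = []
        for _ in range(2000):
            total = 0.0
            for row in e.itertuples():
                fates = rng.rand(row.count) < row.p_day
                total += fates.sum() * row.delta_w_g
            totals.append(total)
        brute_mean = np.mean(totals)
        est = rp.simulate_productivity(df, n_iter=2000, seed=77)
        se = np.hypot(np.std(totals) / np.sqrt(len(totals)),
                      est.sd_g / np.sqrt(est.n_iter))
        assert abs(est.mean_g - brute_mean) < 4 * se
        assert est.expected_g == pytest.approx(
            float((e["count"] * e["delta_w_g"] * e["p_day"]).sum()), rel=1e-12
        )

    def test_split_rows_bit_identical(self):
        """Splitting a count-2k row into two count-k rows leaves the
        simulation unchanged bit for bit (canonical aggregation)."""
        df = _make_assemblage(4, 100, seed=5)
        split = pd.concat(
            [df.assign(count=df["count"] - df["count"] // 2),
             df.assign(count=df["count"] // 2)]
        )
        split = split[split["count"] > 0].reset_index(drop=True)
        a = rp.simulate_productivity(df, n_iter=200, seed=21)
        b = rp.simulate_productivity(split, n_iter=200, seed=21)
        assert a == b

    def test_reproducible_given_seed(self):
        df = _make_assemblage(5, 150, seed=6)
        a = rp.simulate_productivity(df, n_iter=100, seed=3)
        b = rp.simulate_productivity(df.sample(frac=1, random_state=0), n_iter=100, seed=3)
        assert a == b

    def test_subtract_dead_mass_lowers_estimate(self):
        df = _make_assemblage(5, 150, seed=8)
        grow = rp.simulate_productivity(df, n_iter=500, seed=2)
        net = rp.simulate_productivity(df, n_iter=500, seed=2, subtract_dead_mass=True)
        assert net.expected_g < grow.expected_g


class TestSurveySummaries:
    def test_unit_arithmetic_100g_on_100m2(self):
        """One 100 g fish on 100 m^2 is exactly 0.01 t/ha standing biomass."""
        surveys = pd.DataFrame(
            [{"survey_id": "sv", "site_id": "s", "exposure": "sheltered",
              "area_m2": 100.0}]
        )
        L = 10.0
        a = 100.0 / L**3  # makes W exactly 100 g
        obs = pd.DataFrame(
            [{"survey_id": "sv", "species_id": "sp", "length_cm": L, "count": 1,
              "family": "F", "diel_group": "diurnal", "lw_a": a, "lw_b": 3.0,
              "l_max_cm": 40.0, "k_max_per_yr": 0.5}]
        )
        summ = rp.survey_summaries(obs, surveys, n_iter=10, seed=0)
        g = group_rows(summ)
        row = g[(g["diel_group"] == "diurnal")].iloc[0]
        assert row["biomass_t_ha"] == pytest.approx(0.01, rel=1e-12)

    def test_family_rows_sum_to_group_rows(self, small_summaries):
        fam = family_rows(small_summaries)
        grp = group_rows(small_summaries)
        fsum = fam.groupby(["survey_id", "diel_group"])[
            ["biomass_t_ha", "prod_g_100m2_d"]
        ].sum()
        gsum = grp.set_index(["survey_id", "diel_group"])[
            ["biomass_t_ha", "prod_g_100m2_d"]
        ]
        joined = fsum.join(gsum, lsuffix="_fam", rsuffix="_grp", how="inner")
        np.testing.assert_allclose(
            joined["biomass_t_ha_fam"], joined["biomass_t_ha_grp"], rtol=1e-9
        )
        np.testing.assert_allclose(
            joined["prod_g_100m2_d_fam"], joined["prod_g_100m2_d_grp"], rtol=1e-9
        )

    def test_empty_stratum_rows_retained(self, toy_traits, toy_diel, toy_surveys):
        obs = pd.DataFrame(
            [{"survey_id": "sv1", "species_id": "spB", "length_cm": 12.0, "count": 2}]
        )
        enriched, _ = rp.join_observations(obs, toy_traits, rp.pool_diel(toy_diel))
        summ = rp.survey_summaries(enriched, toy_surveys, n_iter=10, seed=0)
        g = group_rows(summ)
        noct = g[(g["survey_id"] == "sv1") & (g["diel_group"] == "nocturnal")]
        assert len(noct) == 1
        assert noct.iloc[0]["biomass_t_ha"] == 0.0
        assert noct.iloc[0]["prod_g_100m2_d"] == 0.0

    def test_kmax_to_zero_kills_productivity_not_biomass(self, toy_enriched, toy_surveys):
        base = rp.survey_summaries(toy_enriched, toy_surveys, n_iter=50, seed=1)
        frozen = toy_enriched.assign(k_max_per_yr=1e-12)
        out = rp.survey_summaries(frozen, toy_surveys, n_iter=50, seed=1)
        g0, g1 = group_rows(base), group_rows(out)
        np.testing.assert_allclose(g1["biomass_t_ha"], g0["biomass_t_ha"], rtol=1e-12)
        assert (g1["prod_g_100m2_d"] < 1e-8).all()

    def test_bit_for_bit_reproducible_and_order_invariant(self, toy_enriched, toy_surveys):
        a = rp.survey_summaries(toy_enriched, toy_surveys, n_iter=100, seed=4)
        shuffled = toy_enriched.sample(frac=1, random_state=1)
        b = rp.survey_summaries(shuffled, toy_surveys, n_iter=100, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_monte_carlo_z_scores_centered(self):
        """Standardized deviations (mean - expectation)/SE over many seeds
        behave like a standard normal sample."""
        df = _make_assemblage(8, 300, seed=10)
        z = []
        for seed in range(50):
            est = rp.simulate_productivity(df, n_iter=200, seed=seed)
            se = est.sd_g / np.sqrt(est.n_iter)
            z.append((est.mean_g - est.expected_g) / se)
        z = np.array(z)
        assert abs(z.mean()) < 0.5
        assert 0.4 < z.std() < 1.8
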