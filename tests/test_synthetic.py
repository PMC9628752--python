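"""The SBR simulator and the seeded synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from ppblight.kinetics import washout_rate
from ppblight.synthetic import (
    PAPER_IRRADIANCES,
    KineticParams,
    LightModelParams,
    NoiseModel,
    PigmentResponse,
    SBRConfig,
    child_seeds,
    generate_community_series,
    generate_growth_rate_dataset,
    generate_protein_table,
    generate_spectrum,
    simulate_condition,
    simulate_cycle,
)


class TestSBRConfig:
    def test_cycle_length_is_sum_of_phases(self):
        cfg = SBRConfig()
        assert cfg.cycle_length_h == pytest.approx(510 / 60)

    def test_purge_fraction(self):
        cfg = SBRConfig()
        assert cfg.purge_fraction == pytest.approx(8.5 / 31)

    def test_srt_shorter_than_cycle_rejected(self):
        with pytest.raises(ValueError):
            SBRConfig(srt_h=1.0)


class TestSimulateCycle:
    def test_dark_no_growth(self):
        cfg, par = SBRConfig(), KineticParams(Ks_acetate=5.0)
        cyc = simulate_cycle(cfg, par, X0=0.5, S0=3.0, irradiance=0.0)
        # tiny residual growth only (logistic tail at x=0)
        assert cyc.biomass[-1] == pytest.approx(0.5, rel=0.05)
        assert cyc.acetate[-1] == pytest.approx(3.0, rel=0.2)

    def test_no_substrate_no_growth(self):
        cfg, par = SBRConfig(), KineticParams()
        cyc = simulate_cycle(cfg, par, X0=0.5, S0=0.0, irradiance=350.0)
        assert cyc.biomass[-1] == pytest.approx(0.5, rel=1e-9)

    def test_matches_exponential_closed_form_in_non_depleting_limit(self):
        cfg = SBRConfig(react_min=60.0)  # short horizon
        par = KineticParams()
        S0 = 100.0  # effectively non-depleting
        cyc = simulate_cycle(cfg, par, X0=0.1, S0=S0, irradiance=350.0)
        mu = par.light_model.mu(350.0) * S0 / (par.Ks_acetate + S0)
        expected = 0.1 * np.exp(mu * cyc.time[-1])
        assert cyc.biomass[-1] == pytest.approx(expected, rel=1e-3)

    def test_mass_balance_within_reaction_phase(self):
        cfg, par = SBRConfig(), KineticParams()
        cyc = simulate_cycle(cfg, par, X0=0.4, S0=3.35, irradiance=264.0)
        dX = cyc.biomass[-1] - cyc.biomass[0]
        dS = cyc.acetate[0] - cyc.acetate[-1]
        assert dX == pytest.approx(par.yield_gVSS_per_mmol * dS, rel=5e-3)

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            simulate_cycle(SBRConfig(), KineticParams(), 0.5, 3.0, 100.0, dt_min=0.0)


class TestSimulateCondition:
    def test_high_light_acetate_limited_steady_state(self):
        sim = simulate_condition(SBRConfig(), KineticParams(), 350.0)
        assert sim.converged
        assert sim.steady_acetate < 0.1
        assert 0.1 < sim.steady_biomass < 5.0

    def test_low_light_residual_acetate_and_washout(self):
        sim = simulate_condition(SBRConfig(), KineticParams(), 3.0)
        assert sim.steady_acetate > 2.0
        assert sim.steady_biomass < 0.05
        assert not sim.converged  # washout never settles

    def test_dark_geometric_decline_by_purge_fraction(self):
        cfg = SBRConfig()
        par = KineticParams(
            light_model=LightModelParams(a=0.25, b=0.05, c=189.0), Ks_acetate=1e6
        )  # huge Ks: effectively zero growth everywhere
        sim = simulate_condition(cfg, par, 0.0, n_cycles=5, X0=1.0)
        ends = [float(c.biomass[-1]) for c in sim.cycles]
        # consecutive end-of-cycle biomass ratios equal the retained fraction
        for a, b in zip(ends, ends[1:]):
            assert b / a == pytest.approx(1 - cfg.purge_fraction, rel=1e-3)

    def test_steady_biomass_monotone_in_irradiance(self):
        res = [
            simulate_condition(SBRConfig(), KineticParams(), irr).steady_biomass
            for irr in sorted(PAPER_IRRADIANCES)
        ]
        for lo, hi in zip(res, res[1:]):
            assert hi >= lo * (1 - 1e-9)

    def test_noise_seed_determinism(self):
        kw = dict(n_cycles=10, noise=NoiseModel(0.05, seed=123))
        a = simulate_condition(SBRConfig(), KineticParams(), 175.0, **kw)
        b = simulate_condition(SBRConfig(), KineticParams(), 175.0, **kw)
        for ca, cb in zip(a.cycles, b.cycles):
            assert np.array_equal(ca.biomass, cb.biomass)
            assert np.array_equal(ca.acetate, cb.acetate)


class TestGrowthRateDataset:
    def test_zero_noise_exact_logistic(self):
        lm = LightModelParams()
        df = generate_growth_rate_dataset(lm, [0, 100, 200], replicates=2, noise_sigma=0.0)
        assert np.allclose(df.mu_h, lm.mu(df.x))

    def test_seed_reproducibility(self):
        lm = LightModelParams()
        a = generate_growth_rate_dataset(lm, PAPER_IRRADIANCES, seed=7)
        b = generate_growth_rate_dataset(lm, PAPER_IRRADIANCES, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_recovery_experiment(self):
        from ppblight.kinetics import LightResponseModel

        lm = LightModelParams(a=0.25, b=0.025, c=189.0)
        errs = []
        for seed in range(40):
            df = generate_growth_rate_dataset(
                lm, PAPER_IRRADIANCES, replicates=3, noise_sigma=0.01, seed=seed
            )
            res = LightResponseModel(df.x, df.mu_h).fit()
            errs.append(abs(res.a - 0.25))
        assert np.median(errs) < 0.02


class TestSpectrumGenerator:
    def test_zero_fractions_flat_noise_only(self):
        scan = generate_spectrum({"bacteriochlorophyll_a": 0.0, "lycopene": 0.0})
        assert np.all(np.abs(scan.absorbance) < 1e-12)

    def test_peak_height_linear_in_mass_fraction(self):
        s1 = generate_spectrum({"lycopene": 1.5}, noise_cv=0.0)
        s2 = generate_spectrum({"lycopene": 3.0}, noise_cv=0.0)
        i = np.argmin(np.abs(s1.wavelengths - 473))
        assert s2.absorbance[i] == pytest.approx(2 * s1.absorbance[i], rel=1e-9)

    def test_determinism(self):
        a = generate_spectrum({"bacteriochlorophyll_a": 2.0}, seed=11)
        b = generate_spectrum({"bacteriochlorophyll_a": 2.0}, seed=11)
        assert np.array_equal(a.absorbance, b.absorbance)

    def test_pigment_response_monotone_decreasing(self):
        resp = PigmentResponse()
        ws = [resp.mass_fraction(i) for i in sorted(PAPER_IRRADIANCES)]
        assert all(b < a for a, b in zip(ws, ws[1:]))
        assert resp.mass_fraction(0.0) == pytest.approx(3.8)
        assert resp.mass_fraction(1e9) == pytest.approx(0.8, abs=1e-3)


class TestProteinTableGenerator:
    def test_zero_sigma_null_gives_p_one_everywhere(self):
        from ppblight.proteomics import DifferentialExpression

        tbl = generate_protein_table(n_proteins=50, lognormal_sigma=0.0, seed=0)
        res = DifferentialExpression(tbl, reference=87).fit()
        assert np.allclose(res.records.p_value, 1.0)

    def test_injected_effect_recovered(self):
        from ppblight.proteomics import DifferentialExpression

        tbl = generate_protein_table(
            n_proteins=500,
            category_effects={"lh": {15: 2.0}},
            category_sizes={"lh": 10},
            seed=4,
        )
        res = DifferentialExpression(tbl, reference=87).fit()
        summ = res.category_summary()
        row = summ[(summ.category == "lh") & (summ.condition == 15)]
        assert row.log2fc_mean.iloc[0] == pytest.approx(2.0, abs=0.3)

    def test_determinism(self):
        a = generate_protein_table(n_proteins=30, seed=2)
        b = generate_protein_table(n_proteins=30, seed=2)
        pd.testing.assert_frame_equal(a.areas, b.areas)


class TestCommunity:
    def test_single_taxon_always_one(self):
        out = generate_community_series(
            {"solo": LightModelParams()}, SBRConfig(), irradiances=[100.0], n_srt=2
        )
        assert np.allclose(out.relative_abundance, 1.0)

    def test_faster_grower_dominance_monotone(self):
        taxa = {
            "fast": LightModelParams(a=0.25, b=0.025, c=150.0),
            "slow": LightModelParams(a=0.10, b=0.025, c=150.0),
        }
        out = generate_community_series(taxa, SBRConfig(), irradiances=[350.0], n_srt=4)
        fast = out[out.taxon == "fast"].sort_values("cycle").relative_abundance
        assert fast.is_monotonic_increasing
        assert fast.iloc[-1] > 0.9

    def test_dark_taxon_declines_by_purge_fraction(self):
        cfg = SBRConfig()
        out = generate_community_series(
            {"a": LightModelParams(), "b": LightModelParams()},
            cfg,
            irradiances=[0.0],
            n_srt=1,
        )
        # both wash out identically, so relative abundance stays 0.5
        assert np.allclose(out.relative_abundance, 0.5)

    def test_requires_taxa(self):
        with pytest.raises(ValueError):
            generate_community_series({}, SBRConfig())


class TestSeeds:
    def test_child_seeds_deterministic_and_bounded(self):
        a = child_seeds(5, 8)
        assert a == child_seeds(5, 8)
        assert all(0 <= s < 2**31 - 1 for s in a)
        assert len(set(a)) == len(a)


def test_washout_thresholds_continuous_vs_discrete():
    """The continuous 1/SRT rule linearises the discrete cycle balance: a
    culture growing at exactly the discrete critical rate
    -ln(1 - f)/T_react is stationary, and the first-order (small-f,
    growth-over-the-whole-cycle) approximation of that rate is 1/SRT."""
    cfg = SBRConfig()
    f = cfg.purge_fraction
    t_react = cfg.react_min / 60.0
    mu_crit = -np.log(1 - f) / t_react
    assert np.exp(mu_crit * t_react) * (1 - f) == pytest.approx(1.0, rel=1e-12)
    # linearised: mu * t_cycle = f  =>  mu = 1/SRT
    assert f / cfg.cycle_length_h == pytest.approx(washout_rate(cfg.srt_h), rel=1e-12)
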