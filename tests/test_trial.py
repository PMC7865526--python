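"""Virtual populations and the coupled dissolution-transit-PK simulation."""

import math

import numpy as np
import pytest

from conftest import bateman_chain

from ivivsim.dissolution import FirstOrderParams
from ivivsim.drugs import builtin_drug_spec
from ivivsim.pk import OneCompartmentParams
from ivivsim.transit import get_transit_scenario
from ivivsim.trial import (
    SAMPLING_SCHEMES,
    DrugModelSpec,
    VariabilitySpec,
    cv_to_sigma,
    draw_population,
    observe,
    simulate_profile,
)


def uniform_spec(m0=1.0, kd=0.05, kat=0.02, cl=200.0, v1=8000.0, dose=100.0):
    """One-compartment drug with identical dissolution in every medium."""
    params = FirstOrderParams(m0, kd)
    return DrugModelSpec(
        name="probe",
        dose_mg=dose,
        disposition=OneCompartmentParams(cl_f=cl, v1_f=v1, ka=kat),
        kat=kat,
        dissolution={"T": {ph: params for ph in (1.2, 4.5, 6.8)},
                     "R": {ph: params for ph in (1.2, 4.5, 6.8)}},
    )


class TestDrawPopulation:
    def test_zero_cv_reproduces_typical_values(self):
        spec = builtin_drug_spec("amlodipine")
        pop = draw_population(4, spec, VariabilitySpec(0, 0, 0), seed=1)
        for subj in pop:
            for period in subj.period_params:
                assert period == spec.typical_params()

    def test_seed_reproducibility(self):
        spec = builtin_drug_spec("irbesartan")
        var = VariabilitySpec(10, 10, 5)
        a = draw_population(12, spec, var, seed=7)
        b = draw_population(12, spec, var, seed=7)
        assert a == b

    def test_sequences_balanced(self):
        pop = draw_population(24, builtin_drug_spec("amlodipine"),
                              VariabilitySpec(5, 5), seed=3)
        seqs = [s.sequence for s in pop]
        assert seqs.count("TR") == seqs.count("RT") == 12

    def test_sample_cv_matches_target(self):
        spec = builtin_drug_spec("amlodipine")
        pop = draw_population(2000, spec, VariabilitySpec(bsv_cv=5, wsv_cv=0), seed=11)
        cl = np.array([s.period_params[0]["cl_f"] for s in pop])
        cv = cl.std(ddof=1) / cl.mean() * 100
        assert cv == pytest.approx(5.0, abs=0.5)

    def test_odd_n_rejected(self):
        with pytest.raises(ValueError, match="even"):
            draw_population(13, builtin_drug_spec("amlodipine"),
                            VariabilitySpec(), seed=0)

    def test_cv_sigma_conversion(self):
        assert cv_to_sigma(0) == 0
        assert cv_to_sigma(10) == pytest.approx(math.sqrt(math.log(1.01)))


class TestSimulateProfile:
    def test_zero_dose_gives_zero_profile(self):
        spec = uniform_spec(dose=0.0)
        prof = simulate_profile(spec.typical_params(), "T", spec,
                                get_transit_scenario(1))
        assert np.all(prof.concentrations == 0)

    def test_matches_three_exponential_chain_solution(self):
        # single effective segment: identical media everywhere, absorption on
        # from t=0, no lag -> dissolution/absorption/elimination is a pure
        # first-order chain with an independent closed form
        spec = uniform_spec(m0=1.0, kd=0.05, kat=0.02, cl=200.0, v1=8000.0)
        kel = 200.0 / 8000.0
        grid = np.arange(0.0, 721.0, 1.0)
        prof = simulate_profile(
            spec.typical_params(), "T", spec, get_transit_scenario(1),
            t_grid=grid, stomach_absorption_scale=1.0,
        )
        oracle = bateman_chain(grid, 100.0, (0.05, 0.02, kel)) / 8000.0
        cmax = oracle.max()
        np.testing.assert_allclose(prof.concentrations, oracle,
                                   rtol=1e-6, atol=cmax * 1e-9)

    def test_fast_dissolution_limit_recovers_oral_curve(self):
        # kd >> kat: profile converges to the classic one-compartment oral
        # curve with rate kat; peak at ln(kat/kel)/(kat - kel)
        kat, kel = 0.0149, 370.0 / 1300.0 / 10  # kel = 0.02846
        spec = uniform_spec(m0=1.0, kd=1000 * kat, kat=kat, cl=370.0,
                            v1=1300.0 * 10, dose=10.0)
        grid = np.arange(0.0, 720.0, 0.05)
        prof = simulate_profile(
            spec.typical_params(), "T", spec, get_transit_scenario(1),
            t_grid=grid, stomach_absorption_scale=1.0,
        )
        oracle = bateman_chain(grid, 10.0, (kat, kel)) / 13000.0
        assert np.max(np.abs(prof.concentrations - oracle)) / oracle.max() < 5e-3
        tmax_theory = math.log(kat / kel) / (kat - kel)
        tmax_sim = grid[prof.concentrations.argmax()]
        assert tmax_sim == pytest.approx(tmax_theory, abs=0.5)

    def test_analytic_and_rk45_backends_agree(self):
        for drug in ("amlodipine", "irbesartan", "hydrochlorothiazide"):
            spec = builtin_drug_spec(drug)
            grid = np.arange(0.0, 1441.0, 5.0)
            kwargs = dict(t_grid=grid)
            a = simulate_profile(spec.typical_params(), "T", spec,
                                 get_transit_scenario(2), **kwargs)
            b = simulate_profile(spec.typical_params(), "T", spec,
                                 get_transit_scenario(2), method="rk45", **kwargs)
            np.testing.assert_allclose(a.concentrations, b.concentrations,
                                       rtol=1e-6, atol=a.concentrations.max() * 1e-7)

    def test_mass_balance(self, rng):
        spec = builtin_drug_spec("hydrochlorothiazide")
        sc = get_transit_scenario(4)
        for _ in range(5):
            params = {k: v * math.exp(rng.normal(0, 0.2))
                      for k, v in spec.typical_params().items()}
            prof = simulate_profile(params, "T", spec, sc)
            dose = spec.dose_mg
            assert np.all(prof.dissolved_cum <= dose + 1e-9)
            assert np.all(np.diff(prof.dissolved_cum) >= -1e-9)
            assert np.all(prof.lumen >= -1e-9)
            absorbed = prof.dissolved_cum - prof.lumen
            in_body = prof.central + (prof.peripheral
                                      if prof.peripheral is not None else 0.0)
            eliminated = absorbed - in_body
            assert np.all(eliminated >= -1e-8)

    def test_longer_gastric_residence_delays_peak(self):
        # with no gastric absorption, a slower-emptying stomach postpones the
        # appearance of drug in plasma and thus Tmax
        spec = builtin_drug_spec("amlodipine")
        grid = np.arange(0.0, 1441.0, 0.5)
        tmaxes = []
        for sid in (1, 2, 3, 4, 5):
            prof = simulate_profile(spec.typical_params(), "T", spec,
                                    get_transit_scenario(sid), t_grid=grid)
            tmaxes.append(grid[prof.concentrations.argmax()])
        assert all(a <= b for a, b in zip(tmaxes, tmaxes[1:]))

    def test_identical_dissolution_gives_identical_products(self):
        spec = uniform_spec()
        sc = get_transit_scenario(1)
        t = simulate_profile(spec.typical_params(), "T", spec, sc)
        r = simulate_profile(spec.typical_params(), "R", spec, sc)
        np.testing.assert_array_equal(t.concentrations, r.concentrations)

    def test_bsv_widens_cmax_dispersion(self):
        spec = builtin_drug_spec("amlodipine")
        sc = get_transit_scenario(1)
        grid = np.arange(0.0, 1441.0, 5.0)

        def cmax_sd(bsv):
            pop = draw_population(20, spec, VariabilitySpec(bsv_cv=bsv), seed=5)
            cmaxes = [
                simulate_profile(s.period_params[0], "T", spec, sc,
                                 t_grid=grid).concentrations.max()
                for s in pop
            ]
            return np.std(cmaxes)

        assert cmax_sd(20) > cmax_sd(5)


class TestObserve:
    def test_schemes_reproduce_published_designs(self):
        assert len(SAMPLING_SCHEMES["sparse"]) == 10
        assert SAMPLING_SCHEMES["sparse"] == (0, 10, 40, 60, 90, 160, 240, 480,
                                              720, 1440)
        assert len(SAMPLING_SCHEMES["typical"]) == 14
        assert len(SAMPLING_SCHEMES["dense"]) == 17
        assert SAMPLING_SCHEMES["dense"][-1] == 1440

    def test_zero_residual_returns_model_values(self):
        spec = builtin_drug_spec("amlodipine")
        prof = simulate_profile(spec.typical_params(), "T", spec,
                                get_transit_scenario(1))
        t, c = observe(prof, "sparse", residual_cv=0.0)
        np.testing.assert_array_equal(
            c, np.interp(t, prof.times, prof.concentrations)
        )

    def test_proportional_error_applied(self):
        spec = builtin_drug_spec("amlodipine")
        prof = simulate_profile(spec.typical_params(), "T", spec,
                                get_transit_scenario(1))
        t, c0 = observe(prof, "sparse", residual_cv=0.0)
        _, c = observe(prof, "sparse", residual_cv=10.0, seed=4)
        assert np.all(c >= 0)
        assert not np.array_equal(c, c0)
        assert c[0] == 0.0  # multiplicative error preserves true zeros

    def test_times_beyond_grid_rejected(self):
        spec = builtin_drug_spec("amlodipine")
        prof = simulate_profile(spec.typical_params(), "T", spec,
                                get_transit_scenario(1),
                                t_grid=np.arange(0.0, 721.0, 1.0))
        with pytest.raises(ValueError, match="outside"):
            observe(prof, "sparse")
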