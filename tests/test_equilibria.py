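"""Mass-action equilibria: species solvers, titration fits, free energy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pscfcs import equilibria as eq, simulate as sim
from pscfcs.exceptions import InvalidArgumentError, UnboundedEstimateError

K_PAPER = 4.6e4  # nM^2
TRIMER = eq.TrimerEquilibrium(K_PAPER)


class TestTrimerSpecies:
    def test_zero_total(self):
        assert eq.trimer_species(TRIMER, 0.0) == (0.0, 0.0, 0.0)

    def test_half_trimerization_at_c_half(self):
        c_half = eq.trimer_c_half(TRIMER)
        s, s3, f = eq.trimer_species(TRIMER, c_half)
        assert f == pytest.approx(0.5, rel=1e-9)
        assert s == pytest.approx(c_half / 2, rel=1e-9)

    def test_no_trimer_limit(self):
        _, _, f = eq.trimer_species(eq.TrimerEquilibrium(1e12), 100.0)
        assert f < 1e-5

    def test_negative_total_rejected(self):
        with pytest.raises(InvalidArgumentError):
            eq.trimer_species(TRIMER, -1.0)

    @given(
        total=st.floats(1e-3, 1e6),
        log_k=st.floats(-2, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_mass_conservation(self, total, log_k):
        """[S] + 3[S3] equals the total to 1e-10 relative for any K."""
        model = eq.TrimerEquilibrium(10.0**log_k)
        s, s3, f = eq.trimer_species(model, total)
        assert abs(s + 3 * s3 - total) / total < 1e-10
        assert 0.0 <= f <= 1.0

    def test_fraction_monotone_in_total_and_affinity(self):
        totals = np.logspace(0, 4, 25)
        fs = [eq.trimer_species(TRIMER, t)[2] for t in totals]
        assert np.all(np.diff(fs) > 0)
        tighter = eq.TrimerEquilibrium(K_PAPER / 10)
        fs2 = [eq.trimer_species(tighter, t)[2] for t in totals]
        assert np.all(np.array(fs2) > np.array(fs))


class TestCHalf:
    def test_paper_constant(self):
        """K = 4.6e4 nM^2 puts the half-trimerization near 2.5e2 nM."""
        assert eq.trimer_c_half(TRIMER) == pytest.approx(247.7, abs=0.5)

    def test_algebraic_identity(self):
        assert eq.trimer_c_half(eq.TrimerEquilibrium(0.75)) == pytest.approx(1.0)

    def test_sqrt_scaling_and_numeric_inversion(self):
        assert eq.trimer_c_half(eq.TrimerEquilibrium(4 * K_PAPER)) == pytest.approx(
            2 * eq.trimer_c_half(TRIMER), rel=1e-12
        )
        # closed form agrees with numeric inversion of the species solver
        c = eq.trimer_c_half(TRIMER)
        assert eq.trimer_species(TRIMER, c)[2] == pytest.approx(0.5, rel=1e-9)


class TestTrimerTitrationFit:
    def test_noiseless_round_trip(self):
        totals = np.logspace(0, 4, 12)
        points = [
            (t, 1 + 2 * eq.trimer_species(TRIMER, t)[2]) for t in totals
        ]
        fitted, _ = eq.fit_trimer_titration(points)
        assert fitted.K == pytest.approx(K_PAPER, rel=1e-6)

    def test_flat_data_flagged_unbounded(self):
        with pytest.raises(UnboundedEstimateError):
            eq.fit_trimer_titration([(1, 1.0), (10, 1.0), (100, 1.0), (1000, 1.0)])

    def test_noisy_recovery_unbiased(self):
        """Across seeded replicates the mean recovered K stays within
        the experimental uncertainty band around the true value."""
        recovered = []
        for seed in range(8):
            table = sim.synth_equilibrium_data(
                "trimer_titration", TRIMER, np.logspace(0, 4, 12), 0.1, 1, seed
            )
            fitted, _ = eq.fit_trimer_titration(
                list(zip(table["concentration"], table["observable"]))
            )
            recovered.append(fitted.K)
        assert np.mean(recovered) == pytest.approx(K_PAPER, rel=0.35)


class TestHill:
    @pytest.mark.parametrize(
        "kd,n,total,expected",
        [
            (550.0, 1.6, 550.0, 0.5),
            (550.0, 1.6, 0.0, 0.0),
            (100.0, 1.0, 300.0, 0.75),
        ],
    )
    def test_fraction_values(self, kd, n, total, expected):
        model = eq.HillBinding(kd, n)
        assert eq.hill_fraction(model, total) == pytest.approx(expected)

    def test_bounded_and_monotone(self):
        model = eq.HillBinding(550.0, 1.6)
        c = np.logspace(0, 5, 50)
        p = eq.hill_fraction(model, c)
        assert np.all((p >= 0) & (p <= 1))
        assert np.all(np.diff(p) > 0)

    def test_noiseless_round_trip(self):
        model = eq.HillBinding(550.0, 1.6)
        c = np.geomspace(50, 8000, 10)
        points = list(zip(c, eq.hill_fraction(model, c)))
        fitted, _ = eq.fit_hill(points)
        assert fitted.k_d == pytest.approx(550.0, rel=1e-6)
        assert fitted.n_hill == pytest.approx(1.6, rel=1e-6)

    def test_langmuir_special_case(self):
        model = eq.HillBinding(200.0, 1.0)
        c = np.geomspace(10, 5000, 8)
        fitted, _ = eq.fit_hill(list(zip(c, eq.hill_fraction(model, c))), n_fixed=1.0)
        assert fitted.k_d == pytest.approx(200.0, rel=1e-6)
        assert fitted.n_hill == 1.0

    def test_flat_data_flagged(self):
        with pytest.raises(UnboundedEstimateError):
            eq.fit_hill([(1, 0.5), (10, 0.5), (100, 0.5), (1000, 0.5)])


class TestSecondTrimer:
    MODEL = eq.SecondTrimerBinding(1.2, TRIMER)

    def test_zero_total(self):
        assert eq.second_trimer_fraction(self.MODEL, 0.0) == 0.0

    def test_half_fraction_at_kd_prime(self):
        """f = 1/2 exactly when the free trimer concentration equals
        K_D'; the required total is found by inverting the trimer
        equilibrium."""
        s3_target_nm = 1.2e3  # nM, equals K_D' = 1.2 uM
        s_free = (s3_target_nm * K_PAPER) ** (1 / 3)
        total_nm = s_free + 3 * s3_target_nm
        f = eq.second_trimer_fraction(self.MODEL, total_nm * 1e-3)
        assert f == pytest.approx(0.5, rel=1e-6)

    def test_bounded_monotone(self):
        totals = np.geomspace(0.01, 50, 40)
        f = eq.second_trimer_fraction(self.MODEL, totals)
        assert np.all((f >= 0) & (f <= 1))
        assert np.all(np.diff(f) > 0)

    def test_noiseless_round_trip(self):
        totals = np.geomspace(0.2, 10, 8)
        points = list(zip(totals, eq.second_trimer_fraction(self.MODEL, totals)))
        fitted, _ = eq.fit_second_trimer(points, TRIMER)
        assert fitted.k_d_prime == pytest.approx(1.2, rel=1e-6)

    def test_all_zero_fractions_flagged(self):
        with pytest.raises(UnboundedEstimateError):
            eq.fit_second_trimer([(0.2, 0), (1, 0), (5, 0), (10, 0)], TRIMER)


class TestFreeEnergy:
    def test_standard_state_zero(self):
        assert eq.binding_free_energy(1.0) == pytest.approx(0.0)

    def test_composed_chaperone_client_constant(self):
        """(K_D,app)^3 / K_tri is a few femtomolar, i.e. about
        -20 kcal/mol at 296 K."""
        k_eff = (550e-12) ** 3 / (K_PAPER * 1e-18)  # molar
        assert k_eff == pytest.approx(3.6e-15, rel=0.01)
        dg = eq.binding_free_energy(k_eff)
        assert dg == pytest.approx(-20.0, abs=0.5)

    def test_logarithm_law(self):
        dg1 = eq.binding_free_energy(1e-9)
        dg2 = eq.binding_free_energy(1e-10)
        rt_ln10 = eq.GAS_CONSTANT_KCAL * 296.15 * np.log(10)
        assert dg1 - dg2 == pytest.approx(rt_ln10, rel=1e-9)

    def test_invalid(self):
        with pytest.raises(InvalidArgumentError):
            eq.binding_free_energy(0.0)


class TestApparentRates:
    def test_ratio_at_half_trimerization(self):
        """With equal rate constants the monomer:trimer pseudo-first-
        order ratio at C_1/2 is [S]:[S3] = 3."""
        c_half = eq.trimer_c_half(TRIMER)
        r_mono, r_tri = eq.apparent_rates(TRIMER, 1.0, 1.0, c_half)
        assert r_mono / r_tri == pytest.approx(3.0, rel=1e-9)

    def test_monomer_dominates_dilute_limit(self):
        r_mono, r_tri = eq.apparent_rates(TRIMER, 1.0, 1.0, 0.01)
        assert r_mono / r_tri > 1e6

    def test_ratio_strictly_decreasing(self):
        totals = np.logspace(0, 4, 30)
        ratios = []
        for t in totals:
            r_mono, r_tri = eq.apparent_rates(TRIMER, 6.7e9, 6.6e9, t)
            ratios.append(r_mono / r_tri)
        assert np.all(np.diff(ratios) < 0)


class TestSynthEquilibriumData:
    def test_zero_noise_equals_model(self):
        model = eq.HillBinding(550.0, 1.6)
        c = np.geomspace(100, 8000, 6)
        table = sim.synth_equilibrium_data("hill", model, c, 0.0, 2, seed=0)
        for rep in (0, 1):
            sub = table[table["replicate"] == rep]
            assert np.allclose(sub["observable"], eq.hill_fraction(model, c))

    def test_midpoint_observable(self):
        model = eq.HillBinding(550.0, 1.6)
        table = sim.synth_equilibrium_data("hill", model, [550.0], 0.0, 1, seed=0)
        assert table["observable"].iloc[0] == pytest.approx(0.5)

    def test_deterministic_under_seed(self):
        t1 = sim.synth_equilibrium_data(
            "trimer_titration", TRIMER, [1, 10, 100, 1000], 0.1, 3, seed=5
        )
        t2 = sim.synth_equilibrium_data(
            "trimer_titration", TRIMER, [1, 10, 100, 1000], 0.1, 3, seed=5
        )
        assert t1.equals(t2)

    def test_unknown_kind(self):
        with pytest.raises(InvalidArgumentError):
            sim.synth_equilibrium_data("langmuir", None, [1.0], 0.0, 1, 0)
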