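"""Population parameters, expectancy and reproductive-value grids.

Closed-form Euler–Lotka solutions, the five internal identities, and full
hand-tally oracle equivalence on tiny cohorts.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from agestage import (
    Cohort,
    NumericError,
    compute_fecundity,
    compute_sxj,
    demographic_params,
    finite_rate,
    identity_report,
    life_expectancy,
    mean_generation_time,
    net_reproductive_rate,
    net_reproductive_rate_two_sex,
    reproductive_value,
)
from agestage.demography import euler_lotka_residual, solve_euler_lotka

from conftest import make_ind, quick_female, quick_male


class TestEulerLotka:
    def test_single_day_schedule_gives_zero_rate(self):
        # exp(-r * 1) * 1 = 1  =>  r = 0
        assert solve_euler_lotka(np.array([1.0])) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_two_day_schedule(self):
        # exp(-2r) * 2 = 1  =>  r = ln(2)/2
        r = solve_euler_lotka(np.array([0.0, 2.0]))
        assert r == pytest.approx(math.log(2) / 2, abs=1e-12)

    def test_residual_below_tolerance(self, sweet_cohort):
        fec = compute_fecundity(sweet_cohort, compute_sxj(sweet_cohort))
        r = solve_euler_lotka(fec.net_maternity)
        assert abs(euler_lotka_residual(r, fec.net_maternity)) < 1e-10

    def test_zero_maternity_raises(self):
        with pytest.raises(NumericError):
            solve_euler_lotka(np.zeros(5))

    @pytest.mark.parametrize("seed", range(6))
    def test_rate_increases_with_fecundity(self, seed):
        rng = np.random.default_rng(seed)
        phi = rng.random(20) * rng.integers(0, 2, 20)
        phi[5] += 1.0
        r1 = solve_euler_lotka(phi)
        bump = phi + rng.random(20) * 0.5  # pointwise increase
        assert solve_euler_lotka(bump) > r1


class TestScalarParams:
    def test_two_sex_identity_from_printed_values(self):
        assert net_reproductive_rate_two_sex(458.0, 39, 100) == pytest.approx(178.62)

    def test_R0_equals_identity_on_cohort(self, sweet_cohort):
        fec = compute_fecundity(sweet_cohort, compute_sxj(sweet_cohort))
        females = sweet_cohort.females()
        F = sum(f.total_eggs() for f in females) / len(females)
        assert net_reproductive_rate(fec) == pytest.approx(
            net_reproductive_rate_two_sex(F, len(females), sweet_cohort.n), abs=1e-10
        )

    def test_finite_rate_and_generation_time_limits(self):
        assert finite_rate(0.0) == 1.0
        assert mean_generation_time(math.e, 1.0) == pytest.approx(1.0)
        with pytest.raises(NumericError):
            mean_generation_time(2.0, 0.0)

    def test_generation_time_consistency_under_rescaling(self, sweet_cohort):
        # T = ln(R0)/r implies a schedule scaled by c has ln(c R0)/r' with the
        # same r' solving the scaled Euler-Lotka equation; check both routes agree
        fec = compute_fecundity(sweet_cohort, compute_sxj(sweet_cohort))
        phi = fec.net_maternity
        for c in (0.5, 2.0):
            r_c = solve_euler_lotka(c * phi)
            T_c = math.log(c * phi.sum()) / r_c
            x1 = np.arange(1, phi.size + 1)
            r_oracle = brentq(lambda r: np.exp(-r * x1) @ (c * phi) - 1.0, -1, 2, xtol=1e-14)
            assert r_c == pytest.approx(r_oracle, abs=1e-10)
            assert T_c == pytest.approx(math.log(c * phi.sum()) / r_oracle, abs=1e-8)


class TestExpectancy:
    def test_everyone_lives_one_day(self):
        c = Cohort(tuple(make_ind(f"x{i}", {"egg": 0}, death=1) for i in range(3)))
        e = life_expectancy(compute_sxj(c)).exj
        assert e[0, 0] == 1.0

    def test_mean_of_two_lifespans(self):
        c = Cohort((make_ind("a", {"egg": 0}, death=2), make_ind("b", {"egg": 0}, death=4)))
        e = life_expectancy(compute_sxj(c)).exj
        assert e[0, 0] == pytest.approx(3.0, abs=1e-12)

    def test_e01_equals_mean_longevity(self, sweet_cohort):
        e = life_expectancy(compute_sxj(sweet_cohort)).exj
        mean_life = np.mean([i.end_day for i in sweet_cohort.individuals])
        assert e[0, 0] == pytest.approx(mean_life, abs=1e-9)
        assert (e >= 0).all()


class TestReproductiveValue:
    def test_zero_fecundity_zero_grid(self):
        c = Cohort((quick_male("m1"), quick_male("m2", death=40)))
        grid = compute_sxj(c)
        fec = compute_fecundity(c, grid)
        v = reproductive_value(grid, fec, 0.0).vxj
        assert np.all(v == 0.0)

    def test_v01_equals_lambda(self, sweet_cohort):
        grid = compute_sxj(sweet_cohort)
        fec = compute_fecundity(sweet_cohort, grid)
        p = demographic_params(sweet_cohort, grid, fec)
        v = reproductive_value(grid, fec, p.r).vxj
        assert abs(v[0, 0] - p.lam) < 1e-6


class TestIdentitySuite:
    @pytest.mark.parametrize("preset", ["sweet", "waxy", "common", "silage"])
    def test_identities_on_presets(self, preset):
        from agestage import cohort_preset, generate_cohort

        c = generate_cohort(cohort_preset(preset, seed=21))
        rep = identity_report(c)
        assert rep["lambda_vs_exp_r"] == 0.0
        assert rep["euler_lotka_residual"] < 1e-10
        assert rep["egg_conservation"] < 1e-9
        assert rep["e01_vs_mean_lifespan"] < 1e-9
        assert rep["v01_vs_lambda"] < 1e-6


class TestTinyCohortOracle:
    """Exhaustive hand-tally equivalence for a 3-individual cohort."""

    def build(self):
        f = quick_female("f", adult_day=28, death=33, eggs={30: 12, 31: 6})
        m = quick_male("m", adult_day=28, death=35)
        d = make_ind("d", {"egg": 0, "instar1": 3}, death=5)
        return Cohort((f, m, d))

    def test_all_parameters_match_hand_tallies(self):
        c = self.build()
        grid = compute_sxj(c)
        fec = compute_fecundity(c, grid)

        # hand tally: eggs 18 total, laid days 30 (12) and 31 (6), N=3
        assert fec.total_eggs == 18
        assert fec.net_maternity[30] == pytest.approx(12 / 3)
        assert fec.net_maternity[31] == pytest.approx(6 / 3)
        R0 = net_reproductive_rate(fec)
        assert R0 == pytest.approx(18 / 3)

        # m_x: l_30 = 2/3 (f and m alive), eggs/alive = 12/2
        assert grid.lx[30] == pytest.approx(2 / 3)
        assert fec.mx[30] == pytest.approx(6.0)

        # independent Euler-Lotka root by brentq on the hand-built schedule
        phi = np.zeros(35)
        phi[30], phi[31] = 4.0, 2.0
        x1 = np.arange(1, 36)
        r_hand = brentq(lambda r: np.exp(-r * x1) @ phi - 1.0, -1, 2, xtol=1e-14)
        p = demographic_params(c, grid, fec)
        assert p.r == pytest.approx(r_hand, abs=1e-10)
        assert p.lam == pytest.approx(math.exp(r_hand))
        assert p.T == pytest.approx(math.log(6.0) / r_hand)

        # e_{0,1} = mean lifespan (33 + 35 + 5)/3
        e = life_expectancy(grid).exj
        assert e[0, 0] == pytest.approx(73 / 3, abs=1e-12)

        # v_{0,1} = lambda
        v = reproductive_value(grid, fec, p.r).vxj
        assert v[0, 0] == pytest.approx(p.lam, abs=1e-9)

        # grid equals full enumeration
        from conftest import census_oracle

        oracle = census_oracle(c)
        total = sum(oracle.values())
        assert grid.counts.sum() == total
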