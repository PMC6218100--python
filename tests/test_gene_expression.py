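"""Transcription-machinery core: rate laws, equilibria and growth scaling."""

import numpy as np
import pytest
from scipy import stats

from sizecycle.gene_expression import (ExpressionState, affinity_sweep,
                                       equilibrium_occupancy, expression_rhs,
                                       simulate_expression,
                                       specific_growth_rate)
from sizecycle.params import ExpressionParams, GenomeConfig


def hand_transcribed_rhs(y, genome, p):
    """Independent transcription of the expression rate laws.

    Deliberately written as one flat formula block, sharing no code with
    the package implementation.
    """
    TM, GITM, GDTM, Vt, Pi, Pd = y
    GI = genome.GIt - GITM
    GD = genome.GDt - GDTM
    dTM = (p.kTmSy * GDTM * genome.GCN / genome.GDt
           + p.kGiTmDs * GITM + p.kGdTmDs * GDTM
           - (p.kGiTmAs / Vt * GI + p.kGdTmAs / Vt * GD) * TM)
    dGITM = p.kGiTmAs / Vt * GI * TM - p.kGiTmDs * GITM
    dGDTM = p.kGdTmAs / Vt * GD * TM - p.kGdTmDs * GDTM
    dVt = p.kVoSy * GDTM * genome.GCN / genome.GDt
    dPi = p.kPiSy * GITM * genome.GCN / genome.GIt - p.kPiDe * Pi
    dPd = p.kPdSy * GDTM * genome.GCN / genome.GDt - p.kPdDe * Pd
    return np.array([dTM, dGITM, dGDTM, dVt, dPi, dPd])


class TestExpressionRhs:
    def test_no_active_size_dependent_genes_means_no_growth(self, dil):
        params, genome = dil
        state = ExpressionState(TM=0.0, GITM=0.5, GDTM=0.0)
        dy = expression_rhs(state, genome, 25.0, params)
        assert dy[3] == 0.0  # dVt/dt: no growth without active GD genes
        # TM synthesis is off; only release from GITM feeds free TM
        assert dy[0] == pytest.approx(params.kGiTmDs * 0.5)

    def test_without_binding_only_degradation_remains(self, dil):
        params, genome = dil
        import dataclasses
        p = dataclasses.replace(params, kGiTmAs=0.0, kGdTmAs=0.0,
                                kGiTmDs=1.0, kGdTmDs=1.0)
        state = ExpressionState(TM=2.0, GITM=0.0, GDTM=0.0)
        dy = expression_rhs(state, genome, 25.0, p, Pi=4.0, Pd=0.0)
        assert dy[4] == pytest.approx(-p.kPiDe * 4.0)
        assert np.allclose(dy[[1, 2, 3]], 0.0)

    def test_matches_hand_transcription(self, dil, rng):
        params, genome = dil
        for _ in range(25):
            y = np.array([rng.uniform(0, 5), rng.uniform(0, genome.GIt),
                          rng.uniform(0, genome.GDt), rng.uniform(5, 60),
                          rng.uniform(0, 20), rng.uniform(0, 20)])
            got = expression_rhs(ExpressionState(*y[:3]), genome, y[3],
                                 params, y[4], y[5])
            want = hand_transcribed_rhs(y, genome, params)
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)

    @pytest.mark.parametrize("Vt", [0.0, -1.0])
    def test_nonpositive_volume_is_a_domain_error(self, dil, Vt):
        params, genome = dil
        with pytest.raises(ValueError):
            expression_rhs(ExpressionState(1.0, 0.1, 1.0), genome, Vt, params)

    def test_negative_state_is_a_domain_error(self, dil):
        params, genome = dil
        with pytest.raises(ValueError):
            expression_rhs(ExpressionState(-0.1, 0.1, 1.0), genome, 10.0, params)


def relaxation_occupancy(genome, TMtotal, Vt, p):
    """Independent equilibrium oracle: integrate the binding dynamics.

    At fixed total TM the two occupancy ODEs (with free TM eliminated by
    conservation) relax to the unique binding equilibrium; integrating
    them to stationarity is an independent route to the same point that
    the package computes algebraically.
    """
    from scipy.integrate import solve_ivp

    def rhs(t, y):
        gi, gd = y
        tm = TMtotal - gi - gd
        return [p.kGiTmAs / Vt * (genome.GIt - gi) * tm - p.kGiTmDs * gi,
                p.kGdTmAs / Vt * (genome.GDt - gd) * tm - p.kGdTmDs * gd]

    sol = solve_ivp(rhs, (0.0, 1e7), [0.0, 0.0], method="LSODA",
                    rtol=1e-13, atol=1e-14)
    assert sol.success
    gi, gd = sol.y[:, -1]
    # stationarity check: residual fluxes vanish
    assert max(abs(r) for r in rhs(0.0, (gi, gd))) < 1e-9
    return float(gi), float(gd)


class TestEquilibriumOccupancy:
    def test_no_machinery_no_binding(self, dil):
        params, genome = dil
        assert equilibrium_occupancy(genome, 0.0, 20.0, params) == (0.0, 0.0)

    def test_high_affinity_genes_saturate_first(self):
        genome = GenomeConfig(GDt=100, GIt=5, GCN=1, GWt=5, GCt=1)
        p = ExpressionParams(kGiTmAs=100.0, kGiTmDs=1.0, kGdTmAs=1.0, kGdTmDs=1.0)
        gi, gd = equilibrium_occupancy(genome, 10.0, 20.0, p)
        assert gi / genome.GIt > gd / genome.GDt

    def test_agrees_with_relaxation_oracle(self, dil, rng):
        params, genome = dil
        for _ in range(20):
            TMt = rng.uniform(0.5, 80.0)
            Vt = rng.uniform(5.0, 80.0)
            gi, gd = equilibrium_occupancy(genome, TMt, Vt, params)
            bi, bd = relaxation_occupancy(genome, TMt, Vt, params)
            assert gi == pytest.approx(bi, abs=1e-8 * max(1.0, gi))
            assert gd == pytest.approx(bd, abs=max(1e-8 * gd, 1e-6))

    def test_occupancy_monotone_in_total_tm(self, dil):
        params, genome = dil
        totals = np.linspace(0.1, 100.0, 25)
        occ = np.array([equilibrium_occupancy(genome, t, 30.0, params)
                        for t in totals])
        assert np.all(np.diff(occ[:, 0]) > -1e-12)
        assert np.all(np.diff(occ[:, 1]) > -1e-12)


class TestGrowthScaling:
    def test_tm_per_volume_reaches_fixed_point(self, dil):
        params, genome = dil
        sol = simulate_expression(genome, params, (0.0, 500.0))
        tmt = sol.y[0, -1] + sol.y[1, -1] + sol.y[2, -1]
        assert tmt / sol.y[3, -1] == pytest.approx(
            params.kTmSy / params.kVoSy, rel=0.01)

    def test_exponential_growth_at_closed_form_rate(self, dil):
        # asymptotic regime: many size-dependent genes, so neither the
        # Whi5 gene's TM capture nor gene saturation perturbs the rate
        params, _ = dil
        genome = GenomeConfig(GDt=2000, GIt=1, GCN=1, GWt=1, GCt=1)
        V0 = 100.0
        TMt0 = params.kTmSy / params.kVoSy * V0
        gi, gd = equilibrium_occupancy(genome, TMt0, V0, params)
        y0 = np.array([TMt0 - gi - gd, gi, gd, V0, 0.0, 0.0])
        sol = simulate_expression(genome, params, (0.0, 1500.0), y0=y0)
        slope = stats.linregress(sol.t, np.log(sol.y[3])).slope
        assert slope == pytest.approx(specific_growth_rate(params, genome),
                                      rel=0.02)

    def test_growth_saturates_to_linear_in_large_cells(self, dil):
        params, genome = dil
        V0 = 2000.0  # far beyond gene saturation
        TMt0 = 5.0 * genome.GDt
        from sizecycle.gene_expression import equilibrium_occupancy as eq
        gi, gd = eq(genome, TMt0, V0, params)
        assert gd / genome.GDt > 0.97
        y0 = np.array([TMt0 - gi - gd, gi, gd, V0, 0.0, 0.0])
        sol = simulate_expression(genome, params, (0.0, 100.0), y0=y0)
        dV = np.diff(sol.y[3]) / np.diff(sol.t)
        # volume increase is (close to) linear: growth rate almost constant
        assert dV[-1] / dV[0] < 1.05

    def test_copy_number_and_ploidy_sensing(self, dil):
        params, genome = dil
        Vt = 30.0
        TMt = params.kTmSy / params.kVoSy * Vt

        def rates(g):
            gi, gd = equilibrium_occupancy(g, TMt, Vt, params)
            whi5_rate = params.kWhiSy * gi * g.GWt / g.GIt
            cln3_rate = params.kCln3Sy * gd * g.GCt / g.GDt
            return whi5_rate, cln3_rate

        hap = GenomeConfig(GDt=200, GIt=1, GCN=1, GWt=1, GCt=1)
        two_whi5 = GenomeConfig(GDt=200, GIt=2, GCN=1, GWt=2, GCt=1)
        diploid = GenomeConfig(GDt=400, GIt=2, GCN=2, GWt=2, GCt=2)
        dip_one_cln3 = GenomeConfig(GDt=400, GIt=2, GCN=2, GWt=2, GCt=1)

        w_h, c_h = rates(hap)
        w_2, _ = rates(two_whi5)
        w_d, c_d = rates(diploid)
        _, c_d1 = rates(dip_one_cln3)

        # an extra WHI5 copy doubles the (saturated) Whi5 synthesis rate
        assert w_2 == pytest.approx(2 * w_h, rel=0.01)
        # ploidy doubling leaves the size-dependent rate unchanged (up to
        # the few-percent share of TM captured by the extra WHI5 copy) ...
        assert c_d == pytest.approx(c_h, rel=0.05)
        # ... but halving the copy-number-to-ploidy ratio halves it
        assert c_d1 == pytest.approx(0.5 * c_d, rel=1e-9)


class TestAffinitySweep:
    def test_empty_grid_is_a_usage_error(self, dil):
        params, genome = dil
        with pytest.raises(ValueError):
            affinity_sweep([], 100.0, params, genome)

    def test_extremes_and_monotone_interpolation(self, dil):
        params, _ = dil
        # asymptotic regime (see growth-rate test) and a grid from the
        # bulk size-dependent affinity up to the size-independent extreme
        genome = GenomeConfig(GDt=2000, GIt=1, GCN=1, GWt=1, GCt=1)
        grid = [100.0, 500.0, 2000.0, 10000.0]
        mu = specific_growth_rate(params, genome)
        settle = 120.0  # let the protein pools reach their moving quasi-steady state
        horizon = settle + np.log(2.05) / mu
        res = affinity_sweep(grid, horizon, params, genome, n_eval=400, V0=100.0)
        t, Vt = res["t"], res["Vt"]
        k0 = int(np.searchsorted(t, settle))
        k1 = int(np.searchsorted(Vt, 2.0 * Vt[k0])) - 1  # one volume doubling
        conc = res["concentration"]
        rel = conc[:, k1] / conc[:, k0]

        # highest affinity: protein amount ~constant, concentration ~ 1/Vt
        amount = res["protein"][-1]
        assert amount[k1] / amount[k0] < 1.1
        assert rel[-1] == pytest.approx(Vt[k0] / Vt[k1], rel=0.1)
        # lowest affinity (the bulk gene class): concentration constant
        assert rel[0] == pytest.approx(1.0, abs=0.02)
        # concentration decay deepens monotonically with affinity
        assert np.all(np.diff(rel) < 0)


class TestEquilibriumProperties:
    """Property-based checks of the binding equilibrium."""

    from hypothesis import given, settings, strategies as st

    @given(TMt=st.floats(0.01, 200.0), Vt=st.floats(1.0, 200.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conservation_and_bounds_hold_for_any_inputs(self, TMt, Vt):
        from sizecycle.params import DilutionParams
        genome = GenomeConfig(GDt=200, GIt=1, GCN=1, GWt=1, GCt=1)
        p = DilutionParams()
        gi, gd = equilibrium_occupancy(genome, TMt, Vt, p)
        assert 0.0 <= gi <= genome.GIt
        assert 0.0 <= gd <= genome.GDt
        free = TMt - gi - gd
        assert free >= -1e-9 * max(TMt, 1.0)
        # the returned pair is a true equilibrium: detailed balance of
        # binding and release for both gene classes
        c = free / Vt
        assert p.kGiTmAs * c * (genome.GIt - gi) == pytest.approx(
            p.kGiTmDs * gi, rel=1e-6, abs=1e-9)
        assert p.kGdTmAs * c * (genome.GDt - gd) == pytest.approx(
            p.kGdTmDs * gd, rel=1e-6, abs=1e-9)
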