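"""1:1 interaction model: simulation, global fitting, derived
quantities, and the 4PL pH dependence."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from kinergy.kinetics import (DegenerateDataError, FourPLModel,
                              InjectionSchedule, Phase, RateConstants,
                              Sensorgram, derive_affinity, fit_1to1,
                              fit_4pl_ph, fold_change, four_pl, half_life,
                              simulate_1to1)

PON = dict(kon=2.4e4, koff=1.9e-4)     # slow type II binder
PDA = dict(kon=1.6e6, koff=9.2e-3)     # fast type I binder


def single_cycle_schedule(kon=2.4e4, koff=1.9e-4, top=2e-7, n=5,
                          final=8000.0):
    conc = [top / 3.0**i for i in range(n)]
    return InjectionSchedule.single_cycle(conc, contact_time=120.0,
                                          gap=60.0,
                                          final_dissociation=final)


class TestScheduleAndTypes:
    def test_rate_constants_identities(self):
        rc = RateConstants(kon=2.4e4, koff=1.9e-4)
        assert rc.KD == pytest.approx(1.9e-4 / 2.4e4, rel=1e-12)
        assert rc.t_half == pytest.approx(math.log(2) / 1.9e-4, rel=1e-12)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            RateConstants(kon=-1.0, koff=1e-3)
        with pytest.raises(ValueError):
            RateConstants(kon=1e5, koff=0.0)

    def test_schedule_must_be_contiguous(self):
        with pytest.raises(ValueError, match="contiguous"):
            InjectionSchedule((
                Phase("association", 0.0, 100.0, 1e-8),
                Phase("dissociation", 150.0, 100.0, 0.0)))

    def test_dissociation_with_analyte_rejected(self):
        with pytest.raises(ValueError):
            Phase("dissociation", 0.0, 100.0, 1e-8)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            InjectionSchedule(())


class TestSimulate:
    def test_blank_injection_gives_flat_zero_trace(self):
        sched = InjectionSchedule((Phase("association", 0.0, 300.0, 0.0),))
        sg = simulate_1to1(1e5, 1e-3, 50.0, sched, noise_sd=0.0)
        assert np.allclose(sg.response, 0.0)

    def test_association_plateau_is_req(self):
        kon, koff, rmax, c = 1e5, 1e-2, 80.0, 1e-6
        sched = InjectionSchedule((Phase("association", 0.0, 5e4, c),))
        sg = simulate_1to1(kon, koff, rmax, sched, noise_sd=0.0, dt=100.0)
        req = kon * c * rmax / (kon * c + koff)
        assert sg.response[-1] == pytest.approx(req, rel=1e-9)

    def test_req_monotone_in_concentration_and_saturates(self):
        kon, koff, rmax = 1e5, 1e-2, 60.0
        ladder = np.geomspace(1e-9, 1e-3, 12)
        req = kon * ladder * rmax / (kon * ladder + koff)
        assert np.all(np.diff(req) > 0)
        assert req[-1] < rmax
        assert req[-1] == pytest.approx(rmax, rel=1e-2)

    def test_closed_form_matches_ode_integration(self):
        """Piecewise closed-form trace equals a fine-tolerance numerical
        integration of dR/dt = kon*C*(rmax-R) - koff*R."""
        kon, koff, rmax = 5e4, 2e-3, 50.0
        sched = single_cycle_schedule(top=5e-7, final=2000.0)
        sg = simulate_1to1(kon, koff, rmax, sched, noise_sd=0.0, dt=5.0)
        r0, ode_vals = 0.0, []
        for phase in sched.phases:
            mask = (sg.time >= phase.start) & (sg.time < phase.end) \
                if phase is not sched.phases[-1] \
                else (sg.time >= phase.start)
            t_local = sg.time[mask] - phase.start
            c = phase.concentration

            def rhs(_t, r):
                return [kon * c * (rmax - r[0]) - koff * r[0]]

            sol = solve_ivp(rhs, (0.0, phase.duration), [r0],
                            t_eval=t_local, rtol=1e-12, atol=1e-12)
            ode_vals.append(sol.y[0])
            end = solve_ivp(rhs, (0.0, phase.duration), [r0],
                            rtol=1e-12, atol=1e-12)
            r0 = float(end.y[0, -1])
        ode = np.concatenate(ode_vals)
        assert np.max(np.abs(ode - sg.response)) < 1e-6

    def test_noise_seeding(self):
        sched = single_cycle_schedule()
        a = simulate_1to1(**PON, rmax=50, schedule=sched, noise_sd=0.5,
                          seed=7, dt=10)
        b = simulate_1to1(**PON, rmax=50, schedule=sched, noise_sd=0.5,
                          seed=7, dt=10)
        c = simulate_1to1(**PON, rmax=50, schedule=sched, noise_sd=0.5,
                          seed=8, dt=10)
        assert np.array_equal(a.response, b.response)
        assert not np.array_equal(a.response, c.response)

    def test_invalid_inputs_rejected(self):
        sched = single_cycle_schedule()
        with pytest.raises(ValueError):
            simulate_1to1(-1.0, 1e-3, 50, sched)
        with pytest.raises(ValueError):
            simulate_1to1(1e5, 1e-3, 0.0, sched)


class TestGlobalFit:
    def test_noise_free_single_cycle_recovery(self):
        """Noise-free kinetic-titration data regenerate the true rates
        to better than 1%."""
        sched = single_cycle_schedule(final=8000.0)
        sg = simulate_1to1(**PON, rmax=50.0, schedule=sched, noise_sd=0.0,
                           dt=2.0)
        res = fit_1to1(sg)
        assert res.rates.kon == pytest.approx(PON["kon"], rel=0.01)
        assert res.rates.koff == pytest.approx(PON["koff"], rel=0.01)
        assert res.rmax == pytest.approx(50.0, rel=0.01)
        assert res.rates.KD == pytest.approx(7.9e-9, rel=0.01)

    def test_multi_cycle_recovery(self):
        traces = []
        for c in (2e-8, 6e-8, 2e-7):
            sched = InjectionSchedule.multi_cycle(c, contact_time=200.0,
                                                  dissociation=400.0)
            traces.append(simulate_1to1(**PDA, rmax=40.0, schedule=sched,
                                        noise_sd=0.0, dt=1.0))
        res = fit_1to1(traces)
        assert res.rates.kon == pytest.approx(PDA["kon"], rel=0.01)
        assert res.rates.koff == pytest.approx(PDA["koff"], rel=0.01)

    def test_noisy_recovery_monte_carlo(self):
        """Median relative bias of kon/koff stays below 5% across 100
        seeded replicates at 1%-of-rmax noise."""
        sched = single_cycle_schedule(final=8000.0)
        err_on, err_off = [], []
        for seed in range(100):
            sg = simulate_1to1(**PON, rmax=50.0, schedule=sched,
                               noise_sd=0.5, seed=seed, dt=5.0)
            res = fit_1to1(sg)
            err_on.append(abs(res.rates.kon / PON["kon"] - 1.0))
            err_off.append(abs(res.rates.koff / PON["koff"] - 1.0))
        assert np.median(err_on) < 0.05
        assert np.median(err_off) < 0.05

    def test_flat_traces_raise_degenerate(self):
        sched = single_cycle_schedule()
        time = np.arange(0.0, sched.end, 10.0)
        sg = Sensorgram(time=time, response=np.zeros_like(time),
                        schedule=sched)
        with pytest.raises(DegenerateDataError):
            fit_1to1(sg)

    def test_single_concentration_rejected(self):
        sched = InjectionSchedule.multi_cycle(1e-8)
        sg = simulate_1to1(1e5, 1e-3, 50, sched, dt=5.0)
        with pytest.raises(ValueError, match="distinct"):
            fit_1to1(sg)


class TestDerivedQuantities:
    @pytest.mark.parametrize("kon, koff, expected, rel", [
        (2.4e4, 1.9e-4, 7.9e-9, 0.01),     # slow binder: KD 7.9 nM
        (1.6e6, 9.2e-3, 5.75e-9, 0.01),    # fast binder: KD ~5.7 nM
        (1.0, 1.0, 1.0, 1e-12),
    ])
    def test_affinity(self, kon, koff, expected, rel):
        assert derive_affinity(kon, koff) == pytest.approx(expected,
                                                           rel=rel)

    @pytest.mark.parametrize("koff, expected_s", [
        (1.9e-4, 3648.0),                  # ~61 min
        (9.2e-3, 75.3),                    # ~1.3 min
        (math.log(2.0), 1.0),
    ])
    def test_half_life(self, koff, expected_s):
        assert half_life(koff) == pytest.approx(expected_s, rel=5e-3)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            derive_affinity(0.0, 1e-3)
        with pytest.raises(ValueError):
            half_life(-1.0)

    def test_fold_changes(self):
        fast = RateConstants(kon=1.6e6, koff=9.2e-3)
        slow = RateConstants(kon=2.4e4, koff=1.9e-4)
        assert fold_change(fast, slow, "kon") == pytest.approx(66.7,
                                                               rel=0.01)
        # destabilised-by-denaturant vs native affinity: ~10-fold weaker
        loose = RateConstants(kon=2.3e5, koff=1.8e-2)
        assert fold_change(loose, slow, "KD") == pytest.approx(9.9,
                                                               rel=0.01)
        assert fold_change(slow, slow, "koff") == 1.0
        with pytest.raises(ValueError):
            fold_change(fast, slow, "rmax")


class TestFourPL:
    TRUTH = dict(k_low=7 * 2.4e4, k_high=2.4e4, pka=6.25, hill=1.0)

    def _series(self, noise=0.0, seed=0, ph=None):
        rng = np.random.default_rng(seed)
        if ph is None:
            ph = np.linspace(5.5, 7.4, 8)
        k = four_pl(ph, self.TRUTH["k_low"], self.TRUTH["k_high"],
                    self.TRUTH["pka"], self.TRUTH["hill"])
        if noise:
            k = k * np.exp(rng.normal(0.0, noise, size=ph.shape))
        return ph, k

    def test_noise_free_exact_recovery(self):
        ph, k = self._series()
        res = fit_4pl_ph(ph, k)
        assert res.params["pKa"] == pytest.approx(6.25, abs=1e-5)
        assert res.params["k_low_pH"] == pytest.approx(
            self.TRUTH["k_low"], rel=1e-4)
        assert res.params["hill"] == pytest.approx(1.0, abs=1e-4)

    def test_noisy_pka_recovery(self):
        """5% log-normal noise on an 8-point titration leaves the
        recovered pKa within +/-0.15 (median over seeds)."""
        pkas = []
        for seed in range(40):
            ph, k = self._series(noise=0.05, seed=seed)
            pkas.append(fit_4pl_ph(ph, k).params["pKa"])
        assert abs(np.median(pkas) - 6.25) < 0.15

    def test_reorder_invariance(self):
        ph, k = self._series(noise=0.05, seed=3)
        res = fit_4pl_ph(ph, k)
        order = np.array([3, 0, 7, 5, 1, 6, 2, 4])
        res2 = fit_4pl_ph(ph[order], k[order])
        assert res2.params["pKa"] == pytest.approx(res.params["pKa"],
                                                   abs=1e-3)

    def test_flat_data_flagged(self):
        ph = np.linspace(5.5, 7.4, 8)
        res = fit_4pl_ph(ph, np.full(8, 1e5))
        assert not res.reliable
        assert any(w.code == "flat-data" for w in res.warnings)

    def test_grid_search_oracle(self):
        """A brute-force grid over (pKa, hill) at the true plateaus finds
        the same SSE minimum as the optimiser."""
        ph, k = self._series(noise=0.05, seed=11)
        pka_grid = np.linspace(5.8, 6.8, 161)
        hill_grid = np.linspace(0.5, 2.0, 121)
        best, best_sse = None, np.inf
        for pg in pka_grid:
            for hg in hill_grid:
                sse = np.sum((four_pl(ph, self.TRUTH["k_low"],
                                      self.TRUTH["k_high"], pg, hg)
                              - k) ** 2)
                if sse < best_sse:
                    best, best_sse = (pg, hg), sse
        res = fit_4pl_ph(ph, k)
        # free-plateau optimum may differ slightly from the fixed-plateau
        # grid, but the located pKa must agree to the grid resolution
        assert res.params["pKa"] == pytest.approx(best[0], abs=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            FourPLModel([6.0, 6.5, 7.0], [1.0, 2.0, 3.0])


@given(st.floats(1e3, 1e7), st.floats(1e-5, 1e-1))
def test_affinity_halflife_identities(kon, koff):
    rc = RateConstants(kon=kon, koff=koff)
    assert rc.KD * kon == pytest.approx(koff, rel=1e-9)
    assert rc.t_half * koff == pytest.approx(math.log(2.0), rel=1e-9)
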