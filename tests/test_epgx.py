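"""Two-pool EPG-X simulator: closed-form limits, reductions, symmetries and
the isochromat Bloch-McConnell cross-check."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from r2hat.epgx import (
    ConvergenceError,
    ernst_signal,
    ideal_spoiled_steady_state,
    simulate_spgr_steady_state,
)
from r2hat.isochromat import isochromat_oracle
from r2hat.params import ExchangeParams, PoolParams, SequenceParams, two_pool_wm

TIGHT = SequenceParams(ideal_spoiling=True, convergence_tol=1e-12)
FULL = SequenceParams()


def _single_pool(t1=1450.0, t2=36.0):
    return (PoolParams(t1=280.0, t2=8.0, fraction=0.0), PoolParams(t1, t2, 1.0))


class TestErnstLimit:
    @pytest.mark.parametrize("alpha", [6.0, 26.0, 42.0, 90.0])
    def test_single_pool_ideal_spoiling_matches_ernst(self, alpha):
        ps = simulate_spgr_steady_state(_single_pool(), None, TIGHT, alpha)
        assert abs(ps.s_mw) == 0.0
        assert abs(abs(ps.s_ie) - ernst_signal(alpha, TIGHT.tr, 1450.0)) < 1e-9

    @settings(max_examples=10, deadline=None)
    @given(
        alpha=st.floats(2.0, 90.0),
        t1=st.floats(100.0, 3000.0),
        tr=st.floats(5.0, 50.0),
    )
    def test_ernst_over_parameter_space(self, alpha, t1, tr):
        seq = SequenceParams(
            tr=tr, ideal_spoiling=True, convergence_tol=1e-9, n_pulses_max=40_000
        )
        ps = simulate_spgr_steady_state(_single_pool(t1=t1), None, seq, alpha)
        assert abs(abs(ps.s_ie) - ernst_signal(alpha, tr, t1)) < 1e-6

    @pytest.mark.parametrize("mwf,res,alpha", [(0.16, 300.0, 26.0), (0.06, 100.0, 9.0)])
    def test_two_pool_ideal_spoiling_matches_bloch_mcconnell_fixed_point(
        self, mwf, res, alpha
    ):
        """With ideal spoiling each pool's amplitude follows the longitudinal
        Bloch-McConnell steady state mixed by exchange."""
        pools = two_pool_wm(mwf)
        ex = ExchangeParams(res)
        ps = simulate_spgr_steady_state(pools, ex, TIGHT, alpha)
        expected = ideal_spoiled_steady_state(pools, ex, TIGHT.tr, alpha)
        assert abs(abs(ps.s_mw) - expected[0]) < 1e-6
        assert abs(abs(ps.s_ie) - expected[1]) < 1e-6


class TestReductionsAndSymmetries:
    def test_zero_flip_angle_gives_zero_signal_with_warning(self):
        with pytest.warns(UserWarning):
            ps = simulate_spgr_steady_state(two_pool_wm(0.16), ExchangeParams(300.0), FULL, 0.0)
        assert ps.s_mw == 0 and ps.s_ie == 0

    def test_mwf_zero_reduces_to_single_pool(self):
        ps2 = simulate_spgr_steady_state(two_pool_wm(0.0), ExchangeParams(300.0), FULL, 26.0)
        ps1 = simulate_spgr_steady_state(_single_pool(), None, FULL, 26.0)
        assert ps2.s_mw == 0
        assert abs(ps2.s_ie - ps1.s_ie) < 1e-12

    def test_no_exchange_is_superposition_of_independent_pools(self):
        pools = two_pool_wm(0.16)
        both = simulate_spgr_steady_state(pools, None, FULL, 26.0)
        only_mw = simulate_spgr_steady_state(
            (PoolParams(280.0, 8.0, 1.0), PoolParams(1450.0, 36.0, 0.0)), None, FULL, 26.0
        )
        only_ie = simulate_spgr_steady_state(
            (PoolParams(280.0, 8.0, 0.0), PoolParams(1450.0, 36.0, 1.0)), None, FULL, 26.0
        )
        # agreement limited only by the pseudo-steady-state tolerance
        assert abs(both.s_mw - 0.16 * only_mw.s_mw) < 1e-6
        assert abs(both.s_ie - 0.84 * only_ie.s_ie) < 1e-6

    def test_pool_label_swap_leaves_net_signal_unchanged(self):
        pa, pb = two_pool_wm(0.16)
        ex = ExchangeParams(300.0)
        fwd = simulate_spgr_steady_state((pa, pb), ex, FULL, 26.0)
        # swapped labels: forward rate becomes the IE->MW rate
        ex_swapped = ExchangeParams(1.0 / ex.k_ie_to_mw(pa.fraction, pb.fraction))
        rev = simulate_spgr_steady_state((pb, pa), ex_swapped, FULL, 26.0)
        assert abs((fwd.s_mw + fwd.s_ie) - (rev.s_mw + rev.s_ie)) < 1e-10

    @pytest.mark.parametrize("mwf,res,alpha", [(0.16, 300.0, 42.0), (0.02, 100.0, 6.0)])
    def test_total_signal_bounded_by_equilibrium_magnetisation(self, mwf, res, alpha):
        ps = simulate_spgr_steady_state(two_pool_wm(mwf), ExchangeParams(res), FULL, alpha)
        assert abs(ps.s_mw) + abs(ps.s_ie) <= 1.0

    def test_determinism(self):
        a = simulate_spgr_steady_state(two_pool_wm(0.16), ExchangeParams(300.0), FULL, 42.0)
        b = simulate_spgr_steady_state(two_pool_wm(0.16), ExchangeParams(300.0), FULL, 42.0)
        assert a.s_mw == b.s_mw and a.s_ie == b.s_ie and a.n_pulses == b.n_pulses


class TestIsochromatOracle:
    def test_single_pool_ideal_spoiling_matches_ernst(self):
        ps = isochromat_oracle(_single_pool(), None, TIGHT, 26.0, 2000)
        assert abs(abs(ps.s_ie) - ernst_signal(26.0, TIGHT.tr, 1450.0)) < 1e-6

    def test_rejects_too_few_isochromats(self):
        with pytest.raises(ValueError, match="1000"):
            isochromat_oracle(two_pool_wm(0.16), None, FULL, 26.0, 10)

    def test_non_convergence_reports_last_relative_change(self):
        seq = SequenceParams(n_pulses_max=20, convergence_tol=1e-12)
        with pytest.raises(ConvergenceError) as err:
            isochromat_oracle(two_pool_wm(0.16), ExchangeParams(300.0), seq, 6.0, 1000)
        assert np.isfinite(err.value.last_relative_change)

    @pytest.mark.parametrize(
        "mwf,res,alpha",
        [
            (0.16, 300.0, 42.0),  # white-matter condition, full spoiling model
            (0.02, 100.0, 6.0),
            (0.20, 500.0, 19.0),
            (0.10, 200.0, 26.0),
        ],
    )
    def test_epgx_matches_brute_force_bloch_mcconnell(self, mwf, res, alpha):
        """EPG-X and the dephasing-ensemble integration agree to 1e-3
        relative on pool-resolved complex amplitudes."""
        pools = two_pool_wm(mwf)
        ex = ExchangeParams(res)
        epg = simulate_spgr_steady_state(pools, ex, FULL, alpha)
        iso = isochromat_oracle(pools, ex, FULL, alpha, 10_000)
        scale = abs(iso.s_mw + iso.s_ie)
        assert abs(epg.s_mw - iso.s_mw) / scale < 1e-3
        assert abs(epg.s_ie - iso.s_ie) / scale < 1e-3


class TestValidation:
    def test_pool_invariants(self):
        with pytest.raises(ValueError):
            PoolParams(t1=8.0, t2=36.0, fraction=0.5)
        with pytest.raises(ValueError):
            PoolParams(t1=1450.0, t2=36.0, fraction=1.5)
        with pytest.raises(ValueError):
            ExchangeParams(-10.0)
        with pytest.raises(ValueError):
            SequenceParams(flip_angles=(0.0, 91.0))

    def test_detailed_balance_zero_net_flux(self):
        ex = ExchangeParams(250.0)
        f_mw, f_ie = 0.16, 0.84
        assert abs(ex.k_mw_to_ie * f_mw - ex.k_ie_to_mw(f_mw, f_ie) * f_ie) < 1e-18
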