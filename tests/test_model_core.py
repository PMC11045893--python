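"""Per-term evaluators: generalized rates, currents, derivatives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ehhsim as e
from ehhsim.model import RATE_EPS

from conftest import hh_rate_oracles


class TestEvalRate:
    @pytest.mark.parametrize(
        "rate, v, expected",
        [
            # branch 2 at v = k1: exp(0) + 1 = 2
            (e.RateFunction(f_t=2, k0=0.6, k1=-40.0, k2=0.3), -40.0, 0.3),
            # branch 1 with k2 = 0 is constant k0
            (e.RateFunction(f_t=1, k0=0.125, k1=7.0, k2=0.0), 55.0, 0.125),
            (e.RateFunction(f_t=1, k0=0.125, k1=7.0, k2=0.0), -90.0, 0.125),
            # branch 0 equals the classic sodium-activation rate at V=0:
            # 0.1 * 25 / (e^2.5 - 1)
            (e.RateFunction(f_t=0, k0=-0.1, k1=-25.0, k2=-0.1), 0.0,
             2.5 / (math.exp(2.5) - 1.0)),
        ],
    )
    def test_branch_values(self, rate, v, expected):
        assert e.eval_rate(rate, v) == pytest.approx(expected, rel=1e-12)

    def test_affine_wrap_scales_and_offsets(self):
        base = e.RateFunction(f_t=1, k0=2.0, k1=0.0, k2=0.5)
        wrapped = e.RateFunction(f_t=1, k0=2.0, k1=0.0, k2=0.5, a=0.25, b=5.0)
        v = -12.5
        assert e.eval_rate(wrapped, v) == 0.25 * e.eval_rate(base, v) + 5.0

    def test_branch0_with_zero_k2_rejected(self):
        with pytest.raises(e.InvalidParameterError):
            e.RateFunction(f_t=0, k0=1.0, k1=0.0, k2=0.0)

    def test_invalid_branch_selector_rejected(self):
        with pytest.raises(e.InvalidParameterError):
            e.RateFunction(f_t=3, k0=1.0, k1=0.0, k2=1.0)

    def test_singularity_guard_is_continuous(self):
        """Approaching the removable singularity, the evaluated rate
        converges to the analytic limit k0/k2."""
        r = e.RateFunction(f_t=0, k0=-0.01, k1=-10.0, k2=-0.1)
        limit = r.k0 / r.k2
        assert e.eval_rate(r, -10.0) == limit
        diffs = []
        for eps in (RATE_EPS, RATE_EPS / 10, RATE_EPS / 100):
            v = -10.0 + eps / abs(r.k2)  # puts |(k1-v) k2| at eps
            diffs.append(abs(e.eval_rate(r, v) - limit))
        assert diffs[0] < 1e-7 * abs(limit)
        assert diffs[2] <= diffs[1] <= diffs[0]

    def test_array_and_scalar_paths_agree(self):
        v = np.linspace(-100, 100, 401)
        for f_t in (0, 1, 2):
            r = e.RateFunction(f_t=f_t, k0=0.3, k1=-20.0, k2=0.08, a=1.5, b=0.2)
            arr = e.eval_rate(r, v)
            scal = np.array([e.eval_rate(r, float(x)) for x in v])
            # the vectorized exponential may differ from libm by 1 ulp
            np.testing.assert_allclose(arr, scal, rtol=1e-14)


def test_hh_rate_records_match_direct_transcription(hh_model):
    """The preset's generalized-rate records reproduce the six classic
    squid-axon rate equations to 1e-12 relative on a dense grid."""
    grid = np.arange(-110.0, 60.0 + 1e-9, 0.25)
    oracles = hh_rate_oracles()
    comp = hh_model.cells[0].compartments[0]
    for ch in comp.channels:
        for gate in ch.gates:
            a_ref, b_ref = oracles[ch.name, gate.name]
            for rate, ref in ((gate.rate1, a_ref), (gate.rate2, b_ref)):
                got = e.eval_rate(rate, grid)
                want = ref(grid)
                assert np.max(np.abs(got - want) / np.abs(want)) < 1e-12


class TestCurrentTerms:
    @pytest.mark.parametrize(
        "pairs, expected",
        [([(0.5, 4)], 0.0625), ([(0.2, 3), (0.6, 1)], 0.0048), ([], 1.0)],
    )
    def test_gate_product(self, pairs, expected):
        assert e.gate_product(pairs) == pytest.approx(expected, rel=1e-15)

    @settings(derandomize=True, max_examples=50)
    @given(
        ys=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=5),
        bump=st.floats(1e-6, 0.5),
        idx=st.integers(0, 4),
    )
    def test_gate_product_monotone_in_each_gate(self, ys, bump, idx):
        idx = idx % len(ys)
        exps = [1 + (i % 3) for i in range(len(ys))]
        lo = e.gate_product(list(zip(ys, exps)))
        ys_hi = list(ys)
        ys_hi[idx] = min(1.0, ys_hi[idx] + bump)
        hi = e.gate_product(list(zip(ys_hi, exps)))
        assert hi >= lo

    def test_channel_current(self):
        ch = e.ChannelSpec(name="K", g=36.0, e_rev=12.0)
        assert e.channel_current(ch, 10.0, 0.0625) == pytest.approx(-4.5)
        assert e.channel_current(ch, 12.0, 0.3) == 0.0
        assert e.channel_current(e.ChannelSpec(name="x", g=0.0, e_rev=0.0), 5.0, 1.0) == 0.0

    def test_leak_current(self):
        comp = e.CompartmentSpec(name="m", C=1.0, g_leak=0.3, e_leak=-10.613)
        assert e.leak_current(comp, -10.613) == 0.0
        assert e.leak_current(comp, 0.0) == pytest.approx(3.1839, rel=1e-12)
        none = e.CompartmentSpec(name="m", C=1.0, g_leak=0.0, e_leak=3.0)
        assert e.leak_current(none, 100.0) == 0.0


def _chain(n, p_ups, g_int=0.13):
    comps = [e.CompartmentSpec(name=f"c{i}", C=1.0, g_leak=0.0, e_leak=0.0,
                               p_up=p_ups[i]) for i in range(n)]
    return e.CellSpec(compartments=comps, g_int=g_int)


class TestMcCurrent:
    def test_equal_voltages_give_zero(self):
        cell = _chain(3, [1.0, 0.4, 0.6])
        for i in range(3):
            assert e.mc_current(cell, i, [-55.0, -55.0, -55.0]) == 0.0

    def test_single_neighbour_value(self):
        cell = _chain(2, [1.0, 0.2])
        # compartment 1 couples to 0 through p_up = 0.2
        assert e.mc_current(cell, 1, [-50.0, -60.0]) == pytest.approx(-6.5)

    def test_interior_symmetry_cancels(self):
        cell = _chain(3, [1.0, 0.5, 0.5])
        v = [-60.0 - 3.0, -60.0, -60.0 + 3.0]
        assert e.mc_current(cell, 1, v) == pytest.approx(0.0, abs=1e-12)

    def test_pairwise_cancellation_with_uniform_half_ratio(self):
        cell = _chain(4, [1.0, 0.5, 0.5, 0.5])
        v = [-70.0, -61.5, -48.0, -55.0]
        total = sum(e.mc_current(cell, i, v) for i in range(4))
        assert abs(total) < 1e-12

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            e.mc_current(_chain(2, [1.0, 0.5]), 2, [0.0, 0.0])


class TestGapDense:
    def test_zero_weights_and_equal_voltages(self):
        net = e.NetworkModel(
            cells=[e.build_io_cell()] * 3, c0=0.8, c1=-0.01, c2=0.2,
            weights=np.zeros((3, 3)),
        )
        assert np.all(e.gap_current_dense(net, [-60.0, -50.0, -40.0]) == 0.0)
        net2 = e.NetworkModel(
            cells=[e.build_io_cell()] * 3, c0=0.8, c1=-0.01, c2=0.2,
            weights=np.ones((3, 3)),
        )
        assert np.all(e.gap_current_dense(net2, [-60.0, -60.0, -60.0]) == 0.0)

    def test_two_cell_hand_value(self):
        net = e.NetworkModel(
            cells=[e.build_io_cell()] * 2, c0=0.8, c1=-0.01, c2=0.2,
            weights=np.ones((2, 2)),
        )
        i = e.gap_current_dense(net, [10.0, 0.0])
        expect = (0.8 * math.exp(-1.0) + 0.2) * 10.0
        assert i[0] == pytest.approx(expect, rel=1e-12)
        assert i[1] == pytest.approx(-expect, rel=1e-12)

    def test_symmetric_weights_conserve_current(self):
        rng = np.random.default_rng(3)
        n = 17
        w = rng.uniform(0, 1, (n, n))
        w = (w + w.T) / 2
        net = e.NetworkModel(cells=[e.build_io_cell()] * n, c0=0.8, c1=-0.01,
                             c2=0.2, weights=w)
        v = rng.uniform(-70, -40, n)
        cur = e.gap_current_dense(net, v)
        assert abs(cur.sum()) <= 1e-9 * np.abs(cur).sum()

    def test_shape_mismatch_rejected(self):
        net = e.NetworkModel(cells=[e.build_io_cell()] * 2, weights=np.zeros((2, 2)))
        with pytest.raises(e.InvalidParameterError):
            e.gap_current_dense(net, [0.0, 1.0, 2.0])


class TestDerivatives:
    def test_gate_derivative_limits(self):
        g = e.GateSpec(
            name="n", formulation="alpha_beta",
            rate1=e.RateFunction(f_t=1, k0=0.4, k1=0.0, k2=0.0),
            rate2=e.RateFunction(f_t=1, k0=0.7, k1=0.0, k2=0.0),
            exponent=1,
        )
        assert e.gate_derivative(g, 0.0, -50.0) == pytest.approx(0.4)
        assert e.gate_derivative(g, 1.0, -50.0) == pytest.approx(-0.7)

    def test_inf_tau_at_target_and_bad_tau(self):
        g = e.GateSpec(
            name="q", formulation="inf_tau",
            rate1=e.RateFunction(f_t=2, k0=1.0, k1=-80.0, k2=-0.25),
            rate2=e.RateFunction(f_t=1, k0=5.0, k1=0.0, k2=0.0),
            exponent=1,
        )
        inf = e.eval_rate(g.rate1, -70.0)
        assert e.gate_derivative(g, inf, -70.0) == 0.0
        bad = e.GateSpec(
            name="q", formulation="inf_tau",
            rate1=g.rate1,
            rate2=e.RateFunction(f_t=1, k0=-5.0, k1=0.0, k2=0.0),
            exponent=1,
        )
        with pytest.raises(e.InvalidParameterError):
            e.gate_derivative(bad, 0.5, -70.0)

    def test_aux_derivative(self):
        a = e.AuxStateSpec(name="Ca", channel=0, c_current=-3.0, c_self=-0.075)
        assert e.aux_derivative(a, 4.0, -1.0) == pytest.approx(2.7)
        assert e.aux_derivative(a, 0.0, 0.0) == 0.0
        decay = e.AuxStateSpec(name="x", channel=0, c_current=0.0, c_self=-1.0)
        assert e.aux_derivative(decay, 5.0, 123.0) == -5.0

    def test_membrane_derivative(self):
        comp = e.CompartmentSpec(name="m", C=1.0, g_leak=0.0, e_leak=0.0)
        assert e.membrane_derivative(comp, 10.0, 0.0, 0.0) == 10.0
        assert e.membrane_derivative(comp, 7.0, 3.0, 2.0, 1.5, 0.5) == 0.0
        comp2 = e.CompartmentSpec(name="m", C=2.0, g_leak=0.0, e_leak=0.0)
        assert e.membrane_derivative(comp2, 10.0, 4.0, 0.0) == pytest.approx(
            e.membrane_derivative(comp, 10.0, 4.0, 0.0) / 2
        )


class TestSpecValidation:
    def test_two_gap_compartments_rejected(self):
        gap = e.CompartmentSpec(name="d", C=1.0, g_leak=0.0, e_leak=0.0, has_gap=True)
        with pytest.raises(e.InvalidParameterError):
            e.CellSpec(compartments=(gap, gap), g_int=0.1)

    def test_mixed_gap_networks_rejected(self):
        with_gap = e.build_io_cell()
        without = e.build_original_hh().cells[0]
        with pytest.raises(e.InvalidParameterError):
            e.NetworkModel(cells=[with_gap, without], weights=np.zeros((2, 2)))

    def test_weight_diagonal_is_ignored(self):
        net = e.NetworkModel(cells=[e.build_io_cell()] * 2, c0=0.8, c1=-0.01,
                             c2=0.2, weights=np.full((2, 2), 9.0))
        assert np.all(np.diag(net.weights) == 0.0)
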