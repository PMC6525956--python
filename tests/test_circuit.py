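"""Tests for the LIF microcircuit builds and the direction-sweep simulator."""

import numpy as np
import pytest

from stpcircuit import (
    ConnectivityMatrix,
    LIFParams,
    LIFState,
    STPParams,
    STPState,
    build_six_unit,
    build_two_unit,
    compute_current,
    euler_step,
    lif_step,
    make_bar_frame,
    make_direction_sequence,
    run_direction_step,
    run_experiment,
)
from stpcircuit.stimulus import BinaryFrame

LIF = LIFParams()
STF = STPParams(tau_f=750.0, tau_d=50.0, U=0.15, A=0.039)


class TestConnectivity:
    def test_six_unit_default_topology(self):
        net = build_six_unit()
        assert np.array_equal(net.w, net.w.T)
        assert np.all(np.diag(net.w) == 1)
        within, between = net.link_counts()
        assert within > between
        assert between == 1
        assert list(net.subpop_labels) == [1, 1, 1, 2, 2, 2]

    def test_six_unit_no_cross_links_gives_two_cliques(self):
        net = build_six_unit(cross_links=())
        assert net.w[:3, 3:].sum() == 0
        assert net.w[:3, :3].sum() == 9 and net.w[3:, 3:].sum() == 9

    def test_within_subpopulation_cross_link_rejected(self):
        with pytest.raises(ValueError):
            build_six_unit(cross_links=((0, 1),))

    def test_two_unit_is_all_ones_with_distinct_labels(self):
        net = build_two_unit()
        assert np.array_equal(net.w, np.ones((2, 2)))
        assert sorted(net.subpop_labels) == [1, 2]

    def test_asymmetric_matrix_rejected(self):
        w = np.zeros((3, 3), dtype=int)
        w[0, 1] = 1
        with pytest.raises(ValueError):
            ConnectivityMatrix(w=w, subpop_labels=np.array([1, 1, 2]))


class TestCurrent:
    def test_zero_efficacies_give_zero_current(self):
        assert compute_current([1, 1, 1], [0, 0, 0], A=0.039) == 0.0

    def test_single_connection_value(self):
        assert compute_current([1], [0.5], A=0.039) == pytest.approx(0.0195)

    def test_linearity_in_gain(self):
        e = [0.3, 0.1, 0.7]
        w = [1, 0, 1]
        assert compute_current(w, e, 0.078) == pytest.approx(
            2 * compute_current(w, e, 0.039)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_current([1, 1], [0.5], A=1.0)


class TestLIFStep:
    def test_rest_is_fixed_point_at_zero_current(self):
        state, spiked = lif_step(LIFState(V=LIF.V_rest), LIF, I=0.0)
        assert state.V == LIF.V_rest and not spiked

    def test_relaxes_monotonically_to_rest(self):
        state = LIFState(V=-60.0)
        previous = state.V
        for _ in range(50):
            state, spiked = lif_step(state, LIF, I=0.0)
            assert not spiked
            assert LIF.V_rest <= state.V < previous
            previous = state.V

    def test_refractory_holds_at_rest_and_counts_down(self):
        state = LIFState(V=LIF.V_rest, refractory_remaining=LIF.tau_arp)
        state, spiked = lif_step(state, LIF, I=1.0)
        assert not spiked and state.V == LIF.V_rest
        assert state.refractory_remaining == LIF.tau_arp - LIF.dt

    @pytest.mark.parametrize("margin_mV", [2.0, 4.0, 8.0, 16.0, 25.0])
    def test_constant_current_period_matches_closed_form(self, margin_mV):
        """Suprathreshold drive: ISI = tau_arp + tau_m ln((Vinf-Vrest)/(Vinf-theta))."""
        dt = 0.01
        params = LIFParams(dt=dt)
        V_inf = params.theta + margin_mV
        I = (V_inf - params.V_rest) / params.R_m
        state = LIFState(V=params.V_rest)
        spike_times = []
        for k in range(int(300.0 / dt)):
            state, spiked = lif_step(state, params, I)
            if spiked:
                spike_times.append(k * dt)
        isi = np.diff(spike_times)
        analytic = params.tau_arp + params.tau_m * np.log(
            (V_inf - params.V_rest) / (V_inf - params.theta)
        )
        assert abs(isi.mean() - analytic) <= dt


def _reference_step(net, lif, stp, frame, u_pair):
    """Scalar re-implementation of one step via the public single-synapse ops."""
    n = net.n_units
    params = [
        STPParams(tau_f=stp.tau_f, tau_d=stp.tau_d,
                  U=u_pair[0] if net.subpop_labels[j] == 1 else u_pair[1],
                  A=stp.A)
        for j in range(n)
    ]
    syn = [STPState.resting(p) for p in params]
    mem = [LIFState(V=lif.V_rest) for _ in range(n)]
    raster = [[] for _ in range(n)]
    n_steps = int(round(lif.T / lif.dt))
    V_trace = np.empty((n_steps, n))
    for k in range(n_steps):
        syn = [
            euler_step(s, p, spiked=bool(frame.pixels[j, k]), dt=lif.dt)
            for j, (s, p) in enumerate(zip(syn, params))
        ]
        eff = [s.efficacy for s in syn]
        for i in range(n):
            I = compute_current(net.w[i], eff, stp.A)
            mem[i], spiked = lif_step(mem[i], lif, I)
            if spiked:
                raster[i].append(k * lif.dt)
        V_trace[k] = [m.V for m in mem]
    return raster, V_trace


class TestRunDirectionStep:
    def test_silent_frame_fires_no_spikes(self):
        # without presynaptic spikes (u, x) stay at (U, 1), so the current
        # holds at the constant resting value A * W @ U -- subthreshold for
        # moderate release probabilities, hence a silent network
        frame = BinaryFrame(np.zeros((6, 1000)))
        net = build_six_unit()
        res = run_direction_step(net, LIF, STF, frame, (0.5, 0.1))
        assert all(t.size == 0 for t in res.raster)
        assert np.all(res.V_trace < LIF.theta)
        U = np.where(net.subpop_labels == 1, 0.5, 0.1)
        resting_I = STF.A * net.w @ U
        np.testing.assert_allclose(res.I_trace, np.tile(resting_I, (1000, 1)),
                                   rtol=1e-9)

    def test_matches_scalar_reference_ops(self):
        """The vectorized sweep equals composition of the public scalar ops."""
        lif = LIFParams(T=300.0)
        frame = make_bar_frame(40, 50)
        net = build_six_unit()
        res = run_direction_step(net, lif, STF, frame, (0.6, 0.05))
        ref_raster, ref_V = _reference_step(net, lif, STF, frame, (0.6, 0.05))
        np.testing.assert_allclose(res.V_trace, ref_V, atol=1e-9)
        for got, want in zip(res.raster, ref_raster):
            np.testing.assert_allclose(got, want)

    def test_higher_release_probability_dominates(self):
        frame = make_bar_frame(100, 50)
        res = run_direction_step(build_six_unit(), LIF, STF, frame, (0.6, 0.05))
        counts = res.spike_counts()
        assert counts[:3].min() >= counts[3:].max()
        assert counts[:3].sum() > counts[3:].sum()

    def test_two_unit_rasters_identical(self):
        frame = make_bar_frame(100, 50)
        stp = STPParams(tau_f=750.0, tau_d=50.0, U=0.15, A=0.078)
        res = run_direction_step(build_two_unit(), LIF, stp, frame, (0.6, 0.05))
        np.testing.assert_array_equal(res.raster[0], res.raster[1])
        assert res.raster[0].size > 0

    def test_subthreshold_bound_and_refractoriness(self, six_unit_experiment):
        net, seq, results = six_unit_experiment
        for res in results[::25]:
            assert np.all(res.V_trace <= LIF.theta)
            for train in res.raster:
                if train.size > 1:
                    assert np.min(np.diff(train)) >= LIF.tau_arp

    def test_current_nonnegative(self, six_unit_experiment):
        _, _, results = six_unit_experiment
        assert all(np.all(res.I_trace >= 0.0) for res in results[::50])

    def test_frame_with_too_few_rows_rejected(self):
        frame = BinaryFrame(np.zeros((6, 1000)))
        with pytest.raises(ValueError):
            run_direction_step(
                build_six_unit(), LIF, STF,
                type("F", (), {"pixels": frame.pixels[:2]})(), (0.5, 0.1),
            )


class TestRunExperiment:
    def test_empty_sequence(self):
        from stpcircuit import DirectionSequence

        seq = DirectionSequence(frames=[], directions=[], u_pairs=[])
        assert run_experiment(build_six_unit(), LIF, STF, seq) == []

    def test_default_sweep_shape_and_determinism(self):
        seq = make_direction_sequence(n_steps=4)
        a = run_experiment(build_six_unit(), LIF, STF, seq)
        b = run_experiment(build_six_unit(), LIF, STF, seq)
        assert len(a) == 4
        for ra, rb in zip(a, b):
            for x, y in zip(ra.raster, rb.raster):
                np.testing.assert_array_equal(x, y)

    def test_carry_over_state_changes_dynamics(self):
        seq = make_direction_sequence(n_steps=4)
        net = build_six_unit()
        fresh = run_experiment(net, LIF, STF, seq)
        carried = run_experiment(net, LIF, STF, seq, carry_over_state=True)
        assert fresh[0].spike_counts().sum() == carried[0].spike_counts().sum()
        assert any(
            not np.array_equal(f.u_trace, c.u_trace)
            for f, c in zip(fresh[1:], carried[1:])
        )

    def test_recurrent_spikes_flag_changes_dynamics(self):
        seq = make_direction_sequence(n_steps=2)
        net = build_six_unit()
        base = run_experiment(net, LIF, STF, seq)
        rec = run_experiment(net, LIF, STF, seq, recurrent_spikes=True)
        assert any(
            not np.array_equal(b.x_trace, r.x_trace) for b, r in zip(base, rec)
        )
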