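"""LIF microcircuit with STP-gated currents and direction-sweep experiments.

The network is a small population of leaky integrate-and-fire units wired by
a binary, symmetric connectivity matrix (self-connections allowed). Each
presynaptic unit j owns one set of synaptic variables (u_j, x_j), driven by
the external stimulus train of its frame row; the current into unit i is

    I_i(t) = A * sum_j w_ij * u_j(t) * x_j(t)

and the membrane follows  tau_m dV/dt = -(V - V_rest) + R_m * I_i, with a
spike emitted when V >= theta, after which V resets to V_rest and the unit
is refractory for tau_arp.

Two builds are provided: the six-unit motif (two three-unit subpopulations,
densely connected within and sparsely between, giving opposite direction
preferences) and the fully connected two-unit microcircuit (which behaves as
a single subpopulation with perfectly synchronized units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimulus import BinaryFrame, DirectionSequence
from .synapses import STPParams

__all__ = [
    "ConnectivityMatrix",
    "LIFParams",
    "LIFState",
    "SimulationResult",
    "build_six_unit",
    "build_two_unit",
    "compute_current",
    "lif_step",
    "run_direction_step",
    "run_experiment",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Binary symmetric connectivity with per-unit subpopulation labels.

    ``w[i, j] = 1`` iff presynaptic unit j connects to postsynaptic unit i;
    connections are bidirectional, so ``w`` is symmetric. ``subpop_labels``
    assigns each unit to subpopulation 1 or 2 (the label selects which of
    the per-step initial release probabilities the unit's outgoing synapse
    recruits).
    """

    w: np.ndarray
    subpop_labels: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w)
        labels = np.asarray(self.subpop_labels)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("w must be square")
        if not np.isin(w, (0, 1)).all():
            raise ValueError("w entries must be 0 or 1")
        if not np.array_equal(w, w.T):
            raise ValueError("connections are bidirectional: w must be symmetric")
        if labels.shape != (w.shape[0],) or not np.isin(labels, (1, 2)).all():
            raise ValueError("subpop_labels must assign each unit to 1 or 2")
        object.__setattr__(self, "w", w.astype(np.int8))
        object.__setattr__(self, "subpop_labels", labels.astype(int))

    @property
    def n_units(self) -> int:
        return self.w.shape[0]

    def link_counts(self) -> tuple[int, int]:
        """(within, between) undirected link counts, self-links included."""
        same = self.subpop_labels[:, None] == self.subpop_labels[None, :]
        upper = np.triu(self.w, 1)
        within = int(upper[same].sum() + np.diag(self.w).sum())
        between = int(upper[~same].sum())
        return within, between


def build_six_unit(cross_links=((2, 3),)) -> ConnectivityMatrix:
    """Six-unit motif: two fully connected three-unit subpopulations.

    Units 0-2 form subpopulation 1 (right-preferring) and units 3-5 form
    subpopulation 2 (left-preferring); within each subpopulation every
    connection, including self-connections, is present. ``cross_links``
    lists the sparse between-subpopulation pairs (default: one reciprocal
    pair, 2 <-> 3), so within-links always outnumber between-links.
    """
    labels = np.array([1, 1, 1, 2, 2, 2])
    w = np.zeros((6, 6), dtype=np.int8)
    w[:3, :3] = 1
    w[3:, 3:] = 1
    for i, j in cross_links:
        if labels[i] == labels[j]:
            raise ValueError(f"cross link ({i}, {j}) joins units of one subpopulation")
        w[i, j] = w[j, i] = 1
    return ConnectivityMatrix(w=w, subpop_labels=labels)


def build_two_unit() -> ConnectivityMatrix:
    """Two-unit microcircuit: 2 x 2 all-ones (bidirectional + self) wiring.

    The units carry distinct subpopulation labels so that the per-step
    release-probability pair assigns U1 to unit 0's synapse and U2 to unit
    1's, but both units receive every synapse, hence identical currents.
    """
    return ConnectivityMatrix(w=np.ones((2, 2), dtype=np.int8),
                              subpop_labels=np.array([1, 2]))


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire parameters.

    Defaults: threshold theta = -55 mV, V_rest = -70 mV, membrane gain
    R_m = 200 (mV per unit of the dimensionless STP current), tau_m = 30 ms,
    absolute refractory period tau_arp = 2 ms, integration step dt = 1 ms,
    stimulus (step) duration T = 1000 ms.
    """

    theta: float = -55.0
    V_rest: float = -70.0
    R_m: float = 200.0
    tau_m: float = 30.0
    tau_arp: float = 2.0
    dt: float = 1.0
    T: float = 1000.0

    def __post_init__(self) -> None:
        if self.theta <= self.V_rest:
            raise ValueError("threshold theta must exceed V_rest")
        if min(self.tau_m, self.tau_arp, self.dt, self.T) <= 0:
            raise ValueError("tau_m, tau_arp, dt and T must be positive")


@dataclass
class LIFState:
    """Membrane potential (mV) and remaining refractory time (ms)."""

    V: float
    refractory_remaining: float = 0.0


def compute_current(w_row, efficacies, A: float) -> float:
    """STP-gated input current: ``A * sum_j w_ij * u_j * x_j``."""
    w_row = np.asarray(w_row, dtype=float)
    efficacies = np.asarray(efficacies, dtype=float)
    if w_row.shape != efficacies.shape:
        raise ValueError("w_row and efficacies must have equal length")
    return float(A * w_row @ efficacies)


def lif_step(state: LIFState, params: LIFParams, I: float) -> tuple[LIFState, bool]:
    """One forward-Euler LIF update under input current ``I``.

    A refractory unit holds at V_rest while its refractory clock runs down;
    otherwise V moves by ``dt / tau_m * (-(V - V_rest) + R_m * I)`` and, on
    reaching threshold, the unit spikes, resets to V_rest and becomes
    refractory for tau_arp.
    """
    if state.refractory_remaining > 0:
        return (
            LIFState(V=params.V_rest,
                     refractory_remaining=max(state.refractory_remaining - params.dt, 0.0)),
            False,
        )
    V = state.V + params.dt / params.tau_m * (-(state.V - params.V_rest) + params.R_m * I)
    if V >= params.theta:
        return LIFState(V=params.V_rest, refractory_remaining=params.tau_arp), True
    return LIFState(V=V, refractory_remaining=0.0), False


@dataclass
class SimulationResult:
    """Recorded traces of one direction step.

    ``raster`` holds each unit's spike times (ms within the step);
    ``V_trace`` / ``I_trace`` are (n_samples, n_units) membrane and current
    series; ``u_trace`` / ``x_trace`` are the synaptic variables of each
    presynaptic unit. Sample k is taken at time k * dt, after the
    within-step update (synapses first, then currents, then membranes).
    """

    raster: list
    V_trace: np.ndarray
    I_trace: np.ndarray
    u_trace: np.ndarray
    x_trace: np.ndarray
    direction: str
    step_index: int
    times: np.ndarray

    @property
    def n_units(self) -> int:
        return self.V_trace.shape[1]

    def spike_counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.raster])


def run_direction_step(
    net: ConnectivityMatrix,
    lif: LIFParams,
    stp: STPParams,
    frame: BinaryFrame,
    u_pair,
    direction: str = "right",
    step_index: int = 0,
    use_post_jump_u: bool = True,
    recurrent_spikes: bool = False,
    initial_state: dict | None = None,
) -> SimulationResult:
    """Simulate one 1000-ms direction step of the microcircuit.

    At step onset every synapse is (re)initialized at rest with the step's
    initial release probability -- ``U = u_pair[0]`` for subpopulation-1
    units, ``u_pair[1]`` for subpopulation-2 units -- and every membrane at
    V_rest, unless ``initial_state`` (from a previous step, carry-over mode)
    supplies ``{"u": ..., "x": ..., "V": ..., "refr": ...}`` arrays.

    External drive: synapse j's presynaptic train is row j of the frame (a
    pixel value 1 at column k is a spike in the k-th millisecond). With
    ``recurrent_spikes=True`` the unit's own emitted spikes additionally
    trigger jumps on its outgoing synapse at the next time step.

    The per-dt update order is: synapse relaxation and spike jumps, then
    currents, then LIF membranes; all traces are sampled after the update.
    """
    n = net.n_units
    if frame.pixels.shape[0] < n:
        raise ValueError("frame has fewer rows than the network has units")
    rows = frame.pixels[:n].astype(bool)
    n_steps = int(round(lif.T / lif.dt))
    if rows.shape[1] < n_steps:
        raise ValueError("frame columns do not cover T / dt time steps")

    U = np.where(net.subpop_labels == 1, u_pair[0], u_pair[1]).astype(float)
    if not ((U > 0) & (U <= 1)).all():
        raise ValueError("release probabilities must lie in (0, 1]")
    if initial_state is None:
        u = U.copy()
        x = np.ones(n)
        V = np.full(n, lif.V_rest)
        refr = np.zeros(n)
    else:
        u = np.array(initial_state["u"], dtype=float)
        x = np.array(initial_state["x"], dtype=float)
        V = np.array(initial_state["V"], dtype=float)
        refr = np.array(initial_state["refr"], dtype=float)

    W = net.w.astype(float)
    dt, tau_m, tau_f, tau_d = lif.dt, lif.tau_m, stp.tau_f, stp.tau_d
    A = stp.A
    V_trace = np.empty((n_steps, n))
    I_trace = np.empty((n_steps, n))
    u_trace = np.empty((n_steps, n))
    x_trace = np.empty((n_steps, n))
    raster: list[list[float]] = [[] for _ in range(n)]
    fired_prev = np.zeros(n, dtype=bool)

    for k in range(n_steps):
        # (1) synapses: Euler relaxation, then jump terms for this ms's spikes
        u = u + dt * (U - u) / tau_f
        x = x + dt * (1.0 - x) / tau_d
        spk = rows[:, k]
        if recurrent_spikes:
            spk = spk | fired_prev
        if spk.any():
            u_post = u + U * (1.0 - u)
            u_rel = u_post if use_post_jump_u else u
            release = np.where(spk, u_rel * x, 0.0)
            u = np.where(spk, u_post, u)
            x = x - release
        np.clip(u, 0.0, 1.0, out=u)
        np.clip(x, 0.0, 1.0, out=x)
        # (2) currents from the post-update synaptic efficacies
        I = A * (W @ (u * x))
        # (3) membranes
        refractory = refr > 0
        refr = np.where(refractory, np.maximum(refr - dt, 0.0), refr)
        V = np.where(refractory, lif.V_rest,
                     V + dt / tau_m * (-(V - lif.V_rest) + lif.R_m * I))
        fired = ~refractory & (V >= lif.theta)
        t = k * dt  # spike timestamped at the presynaptic column it follows
        for i in np.flatnonzero(fired):
            raster[i].append(t)
        V = np.where(fired, lif.V_rest, V)
        refr = np.where(fired, lif.tau_arp, refr)
        fired_prev = fired
        V_trace[k] = V
        I_trace[k] = I
        u_trace[k] = u
        x_trace[k] = x

    result = SimulationResult(
        raster=[np.array(r) for r in raster],
        V_trace=V_trace, I_trace=I_trace, u_trace=u_trace, x_trace=x_trace,
        direction=direction, step_index=step_index,
        times=np.arange(n_steps) * dt,
    )
    result.final_state = {"u": u, "x": x, "V": V, "refr": refr}
    return result


def run_experiment(
    net: ConnectivityMatrix,
    lif: LIFParams,
    stp: STPParams,
    seq: DirectionSequence,
    use_post_jump_u: bool = True,
    recurrent_spikes: bool = False,
    carry_over_state: bool = False,
) -> list:
    """Run a full direction sweep: one SimulationResult per step, in order.

    Each step reinitializes the synaptic and membrane state with that
    step's release-probability pair (``carry_over_state=True`` instead
    carries (u, x, V) across step boundaries; the step's U still changes).
    The run is fully deterministic given the sequence.
    """
    lif_step_params = lif
    if seq.frames and seq.step_duration != lif.T:
        lif_step_params = LIFParams(
            theta=lif.theta, V_rest=lif.V_rest, R_m=lif.R_m, tau_m=lif.tau_m,
            tau_arp=lif.tau_arp, dt=lif.dt, T=seq.step_duration,
        )
    results = []
    state = None
    for idx, (frame, direction, u_pair) in enumerate(
        zip(seq.frames, seq.directions, seq.u_pairs)
    ):
        res = run_direction_step(
            net, lif_step_params, stp, frame, u_pair,
            direction=direction, step_index=idx,
            use_post_jump_u=use_post_jump_u,
            recurrent_spikes=recurrent_spikes,
            initial_state=state,
        )
        if carry_over_state:
            state = res.final_state
        results.append(res)
    return results
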