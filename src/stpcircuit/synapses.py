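"""Tsodyks-Markram short-term synaptic plasticity dynamics.

Two coupled variables describe a synapse driven by a presynaptic spike train:

* ``u`` -- the running release probability (presynaptic residual calcium).
  Between spikes it relaxes exponentially to its resting value ``U`` with
  time constant ``tau_f``; at each spike it jumps by ``U * (1 - u)``.
* ``x`` -- the fraction of neurotransmitter resources available. Between
  spikes it recovers to 1 with time constant ``tau_d``; at each spike it
  drops by the released fraction ``u * x``.

The instantaneous synaptic efficacy is the product ``u * x``. With
``tau_f >> tau_d`` the synapse facilitates (STF); the reverse gives
depression (STD). Both an exact event-driven evaluation (closed-form
exponentials between spikes) and a fixed-step forward-Euler scheme are
provided, and they agree in the small-step limit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "STPParams",
    "STPState",
    "STPTrajectory",
    "relax",
    "apply_spike",
    "euler_step",
    "simulate_train",
    "validate_spike_train",
]


@dataclass(frozen=True)
class STPParams:
    """Kinetic constants of one synapse.

    Parameters
    ----------
    tau_f : float
        Facilitation recovery time constant of ``u``, in ms.
    tau_d : float
        Depression recovery time constant of ``x``, in ms.
    U : float
        Resting (initial) release probability, in (0, 1].
    A : float
        Multiplicative gain applied to the efficacy when a current is
        generated; dimensionless (current units are absorbed into it).
    """

    tau_f: float = 750.0
    tau_d: float = 50.0
    U: float = 0.15
    A: float = 0.039

    def __post_init__(self) -> None:
        if self.tau_f <= 0 or self.tau_d <= 0:
            raise ValueError("time constants tau_f and tau_d must be positive")
        if not 0 < self.U <= 1:
            raise ValueError(f"U must lie in (0, 1], got {self.U}")
        if self.A <= 0:
            raise ValueError("gain A must be positive")

    @classmethod
    def facilitating(cls, U: float = 0.15) -> "STPParams":
        """Default facilitating (STF) preset: tau_f = 750 ms, tau_d = 50 ms."""
        return cls(tau_f=750.0, tau_d=50.0, U=U, A=0.039)


@dataclass(frozen=True)
class STPState:
    """Instantaneous synaptic variables (u, x), both in [0, 1]."""

    u: float
    x: float

    def __post_init__(self) -> None:
        if not 0 <= self.u <= 1 or not 0 <= self.x <= 1:
            raise ValueError(f"(u, x) must lie in [0, 1]^2, got ({self.u}, {self.x})")

    @property
    def efficacy(self) -> float:
        return self.u * self.x

    @classmethod
    def resting(cls, params: STPParams) -> "STPState":
        """State of an unstimulated synapse: u = U, x = 1."""
        return cls(u=params.U, x=1.0)


def validate_spike_train(times) -> np.ndarray:
    """Return ``times`` as a float array, checking it is a valid spike train.

    A valid train is one-dimensional, nonnegative and nondecreasing.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("spike train must be one-dimensional")
    if t.size and t[0] < 0:
        raise ValueError("spike times must be nonnegative")
    if np.any(np.diff(t) < 0):
        raise ValueError("spike times must be nondecreasing")
    return t


def relax(state: STPState, params: STPParams, dt_elapsed: float) -> STPState:
    """Exact inter-spike relaxation over ``dt_elapsed`` ms.

    ``u`` decays to ``U`` with ``tau_f``; ``x`` recovers to 1 with ``tau_d``::

        u' = U + (u - U) * exp(-dt / tau_f)
        x' = 1 - (1 - x) * exp(-dt / tau_d)
    """
    if dt_elapsed < 0:
        raise ValueError("elapsed time must be nonnegative")
    ef = np.exp(-dt_elapsed / params.tau_f)
    ed = np.exp(-dt_elapsed / params.tau_d)
    return STPState(
        u=params.U + (state.u - params.U) * ef,
        x=1.0 - (1.0 - state.x) * ed,
    )


def apply_spike(
    state: STPState, params: STPParams, use_post_jump_u: bool = True
) -> tuple[STPState, float]:
    """Apply the instantaneous jumps at one presynaptic spike.

    The release probability jumps first, ``u+ = u + U * (1 - u)``; the
    released fraction of resources is then ``release = u+ * x`` (or
    ``u * x`` with the pre-jump reading, ``use_post_jump_u=False``) and
    ``x`` drops by that amount.

    Returns
    -------
    (STPState, float)
        The post-spike state and the released fraction in [0, 1].
    """
    u_post = state.u + params.U * (1.0 - state.u)
    u_for_release = u_post if use_post_jump_u else state.u
    release = u_for_release * state.x
    return STPState(u=min(u_post, 1.0), x=max(state.x - release, 0.0)), release


def euler_step(
    state: STPState,
    params: STPParams,
    spiked: bool,
    dt: float,
    use_post_jump_u: bool = True,
) -> STPState:
    """One forward-Euler update of (u, x) over ``dt`` ms.

    The continuous relaxation is applied first; if ``spiked``, the jump
    terms follow within the same step (this ordering converges to the
    event-driven dynamics as dt -> 0). Results are clamped to [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = state.u + dt * (params.U - state.u) / params.tau_f
    x = state.x + dt * (1.0 - state.x) / params.tau_d
    u = min(max(u, 0.0), 1.0)
    x = min(max(x, 0.0), 1.0)
    if spiked:
        out, _ = apply_spike(STPState(u=u, x=x), params, use_post_jump_u)
        return out
    return STPState(u=u, x=x)


@dataclass
class STPTrajectory:
    """Sampled (u, x) trajectory of one synapse.

    ``times[k] = k * dt``; ``u``, ``x`` and ``efficacy = u * x`` hold the
    state after all spikes up to and including ``times[k]`` have been
    processed. ``n_clamped`` counts samples at which numerical clamping
    to [0, 1] changed a value (exact dynamics never need it).
    """

    times: np.ndarray
    u: np.ndarray
    x: np.ndarray
    n_clamped: int = 0

    @property
    def efficacy(self) -> np.ndarray:
        return self.u * self.x

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.times, self.u, self.x, self.efficacy])
        np.savetxt(
            path, arr, delimiter=",", comments="",
            header="time_ms,u,x,efficacy", fmt="%.10g",
        )


def simulate_train(
    params: STPParams,
    train,
    T: float,
    dt: float,
    mode: str = "event_driven",
    use_post_jump_u: bool = True,
) -> STPTrajectory:
    """Drive one synapse from rest with a presynaptic train and sample (u, x).

    Parameters
    ----------
    params : STPParams
    train : array-like
        Nondecreasing spike times in ms, all within [0, T).
    T : float
        Total duration in ms; the trajectory has ``ceil(T / dt)`` samples
        at times 0, dt, 2*dt, ...
    dt : float
        Sampling (and, in Euler mode, integration) step in ms.
    mode : {"event_driven", "euler"}
        ``event_driven`` uses the closed-form inter-spike relaxation and is
        exact at spike times and samples; ``euler`` advances with forward
        Euler, applying each spike's jumps within the step that contains it.

    Notes
    -----
    In both modes, sample ``k`` reflects every spike with time <= k * dt
    (Euler attributes each spike to the first sample at or after it).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    spikes = validate_spike_train(train)
    if spikes.size and spikes[-1] >= T:
        raise ValueError("all spike times must lie in [0, T)")
    n = int(np.ceil(T / dt))
    times = np.arange(n) * dt
    u_out = np.empty(n)
    x_out = np.empty(n)
    n_clamped = 0

    if mode == "event_driven":
        state = STPState.resting(params)
        t_state = 0.0  # time at which `state` is current
        j = 0
        for k in range(n):
            t_k = times[k]
            while j < spikes.size and spikes[j] <= t_k:
                state = relax(state, params, spikes[j] - t_state)
                state, _ = apply_spike(state, params, use_post_jump_u)
                t_state = spikes[j]
                j += 1
            sampled = relax(state, params, t_k - t_state)
            u_out[k] = sampled.u
            x_out[k] = sampled.x
    elif mode == "euler":
        u = params.U
        x = 1.0
        U, tau_f, tau_d = params.U, params.tau_f, params.tau_d
        j = 0
        # sample 0 is at t=0: no relaxation yet, but spikes at exactly t=0 apply
        for k in range(n):
            if k > 0:
                u += dt * (U - u) / tau_f
                x += dt * (1.0 - x) / tau_d
            while j < spikes.size and spikes[j] <= times[k]:
                u_post = u + U * (1.0 - u)
                release = (u_post if use_post_jump_u else u) * x
                u = u_post
                x -= release
                j += 1
            uc = min(max(u, 0.0), 1.0)
            xc = min(max(x, 0.0), 1.0)
            if uc != u or xc != x:
                n_clamped += 1
            u, x = uc, xc
            u_out[k] = u
            x_out[k] = x
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return STPTrajectory(times=times, u=u_out, x=x_out, n_clamped=n_clamped)
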