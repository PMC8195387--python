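"""Conductance-based leaky integrate-and-fire dynamics with inhibitory STDP.

Membrane potentials follow

    C dV/dt = -gL (V - EL) - g_exc (V - E_exc) - g_inh (V - E_inh) + I_e

with exponentially decaying synaptic conductances. Each neuron receives an
independent external Poisson spike train. Synapses from inhibitory onto
excitatory neurons (IE) are plastic under the symmetric inhibitory STDP rule:
on a pre-synaptic (inhibitory) spike the conductance changes by
eta * (x_post - alpha) and on a post-synaptic spike by eta * x_pre, where x
are per-neuron spike traces with time constant tau_stdp; the rule drives
post-synaptic firing toward the target rate alpha / (2 tau_stdp).

The time-stepped network loop is compiled with numba; a self-contained
xorshift128+ generator carried in the call state keeps runs deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "NeuronParams",
    "ExternalDrive",
    "IstdpParams",
    "KernelState",
    "simulate_interval",
    "istdp_update",
    "poisson_drive",
]


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire constants (capacitance pF, conductances nS,
    potentials mV, times ms)."""

    C: float = 200.0
    g_L: float = 10.0
    E_L: float = -60.0
    E_exc: float = 0.0
    E_inh: float = -80.0
    V_th: float = -50.0
    V_reset: float = -60.0
    t_ref: float = 5.0
    tau_exc: float = 5.0
    tau_inh: float = 10.0
    beta_ca: float = 0.1
    tau_ca: float = 50.0  # seconds

    def __post_init__(self) -> None:
        if not (self.E_inh < self.E_L <= self.V_reset < self.V_th < self.E_exc):
            raise ValueError("require E_inh < E_L <= V_reset < V_th < E_exc")
        if min(self.t_ref, self.tau_exc, self.tau_inh, self.tau_ca) <= 0:
            raise ValueError("time constants must be positive")


@dataclass(frozen=True)
class ExternalDrive:
    """Independent per-neuron Poisson input (rate Hz, conductances nS)."""

    rate: float = 10.0
    g_ext_e: float = 8.0
    g_ext_i: float = 12.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("Poisson rate must be >= 0")


@dataclass(frozen=True)
class IstdpParams:
    """Symmetric inhibitory STDP constants. ``alpha`` sets the target rate
    alpha / (2 tau_stdp); the weight change is expressed in conductance units
    scaled by the unit conductance g_unit."""

    tau_stdp: float = 20.0  # ms
    alpha: float = 0.12
    eta: float = 0.05
    g_unit: float = 0.5  # nS

    @property
    def target_rate_hz(self) -> float:
        return self.alpha / (2.0 * self.tau_stdp * 1e-3)


def istdp_update(
    g: float, event: str, x_pre: float, x_post: float, params: IstdpParams
) -> float:
    """Single-synapse form of the IE plasticity rule (reference semantics).

    ``event`` is "pre" (inhibitory neuron fired) or "post" (excitatory target
    fired). The returned conductance is clipped at zero from below.
    """
    if event == "pre":
        g = g + params.eta * params.g_unit * (x_post - params.alpha)
    elif event == "post":
        g = g + params.eta * params.g_unit * x_pre
    else:
        raise ValueError(f"unknown event {event!r}")
    return max(g, 0.0)


def poisson_drive(
    rate_hz: float, dt_ms: float, connected: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli-thinned Poisson events for one membrane step (reference
    semantics; the compiled kernel draws its own)."""
    p = rate_hz * dt_ms * 1e-3
    return (rng.random(len(connected)) < p) & connected


@dataclass
class KernelState:
    """Mutable per-neuron state passed to the compiled kernel."""

    V: np.ndarray
    g_exc: np.ndarray
    g_inh: np.ndarray
    ca: np.ndarray
    ref_left: np.ndarray
    x: np.ndarray  # STDP spike trace (serves as both pre- and post-trace)
    rng_state: np.ndarray  # xorshift128+ state, shape (2,), uint64

    @classmethod
    def fresh(cls, n: int, params: NeuronParams, seed: int) -> "KernelState":
        ss = np.random.SeedSequence(seed)
        s = ss.generate_state(2, dtype=np.uint64)
        s[s == 0] = 0x9E3779B97F4A7C15
        return cls(
            V=np.full(n, params.E_L),
            g_exc=np.zeros(n),
            g_inh=np.zeros(n),
            ca=np.zeros(n),
            ref_left=np.zeros(n, dtype=np.int64),
            x=np.zeros(n),
            rng_state=s,
        )


@njit(cache=True, inline="always")
def _rand_u(state):
    """xorshift128+ -> double in [0, 1)."""
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0
    s1 ^= s0 >> np.uint64(26)
    state[1] = s1
    return np.float64((s0 + s1) >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=True)
def _simulate(
    n_steps,
    dt_ms,
    # state (in place)
    V, g_exc, g_inh, ca, ref_left, x, rng_state,
    # population & drive
    is_inh, drive_on, g_ext, p_ext, I_ext,
    # connectivity, CSR by source
    indptr, tgt, syn_g,
    # incoming-IE lookup, CSR by target: indices into syn_g plus sources
    ie_indptr, ie_syn, ie_src,
    # neuron constants
    C, gL, EL, Eexc, Einh, Vth, Vres, ref_steps,
    d_exc, d_inh, d_ca, d_x, beta,
    # plasticity switches
    istdp_on, eta_g, alpha,
    # growth integration (3 pools per neuron)
    growth_on, growth_every, dt_growth, z, nu, xi, zeta, omega,
    # spike output
    spk_t, spk_id,
):
    n = V.shape[0]
    n_spikes = 0
    max_spikes = spk_t.shape[0]
    spikers = np.empty(n, dtype=np.int64)
    for step in range(n_steps):
        # conductance / trace decay, external drive, membrane integration
        n_spk = 0
        for i in range(n):
            g_exc[i] *= d_exc
            g_inh[i] *= d_inh
            ca[i] *= d_ca
            x[i] *= d_x
            if drive_on[i] and _rand_u(rng_state) < p_ext:
                g_exc[i] += g_ext[i]
            if ref_left[i] > 0:
                ref_left[i] -= 1
                V[i] = Vres
            else:
                dv = (
                    -gL * (V[i] - EL)
                    - g_exc[i] * (V[i] - Eexc)
                    - g_inh[i] * (V[i] - Einh)
                    + I_ext[i]
                ) * (dt_ms / C)
                V[i] += dv
                if V[i] >= Vth:
                    V[i] = Vres
                    ref_left[i] = ref_steps
                    ca[i] += beta
                    x[i] += 1.0
                    spikers[n_spk] = i
                    n_spk += 1
        # propagate spikes and apply the IE plasticity rule
        for k in range(n_spk):
            s = spikers[k]
            if n_spikes < max_spikes:
                spk_t[n_spikes] = step
                spk_id[n_spikes] = s
                n_spikes += 1
            else:
                return n_spikes, True
            src_inh = is_inh[s]
            for j in range(indptr[s], indptr[s + 1]):
                t = tgt[j]
                if src_inh:
                    if istdp_on and not is_inh[t]:
                        gn = syn_g[j] + eta_g * (x[t] - alpha)
                        syn_g[j] = gn if gn > 0.0 else 0.0
                    g_inh[t] += syn_g[j]
                else:
                    g_exc[t] += syn_g[j]
            if istdp_on and not src_inh:
                for j in range(ie_indptr[s], ie_indptr[s + 1]):
                    syn_g[ie_syn[j]] += eta_g * x[ie_src[j]]
        # element growth at the coarse bookkeeping step
        if growth_on and (step + 1) % growth_every == 0:
            for i in range(n):
                for pcl in range(3):
                    rate = nu[i, pcl] * (
                        2.0 * np.exp(-(((ca[i] - xi[i, pcl]) / zeta[i, pcl]) ** 2))
                        - omega[i, pcl]
                    )
                    zn = z[i, pcl] + rate * dt_growth
                    z[i, pcl] = zn if zn > 0.0 else 0.0
    return n_spikes, False


def simulate_interval(
    duration_s: float,
    dt_ms: float,
    state: KernelState,
    params: NeuronParams,
    *,
    is_inh: np.ndarray,
    drive_on: np.ndarray,
    g_ext: np.ndarray,
    rate_ext_hz: float,
    I_ext: np.ndarray | None = None,
    indptr: np.ndarray,
    tgt: np.ndarray,
    syn_g: np.ndarray,
    ie_indptr: np.ndarray,
    ie_syn: np.ndarray,
    ie_src: np.ndarray,
    istdp: IstdpParams | None = None,
    growth: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None,
    z: np.ndarray | None = None,
    dt_growth_s: float = 0.1,
    max_spike_rate_hz: float = 400.0,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Run the compiled loop for ``duration_s`` seconds of simulated time.

    Returns ``(spike_ids, spike_times_ms, overflow)`` with times relative to
    the interval start. ``overflow`` is raised when the spike buffer — sized
    for ``max_spike_rate_hz`` per neuron — fills up, which signals runaway
    network activity to the caller.

    ``growth`` supplies per-neuron, per-pool Gaussian growth-curve parameter
    arrays ``(nu, xi, zeta, omega)`` (each (N, 3): axonal, post-E, post-I)
    and ``z`` the continuous element counts integrated every
    ``dt_growth_s``.
    """
    n = len(state.V)
    n_steps = int(round(duration_s * 1000.0 / dt_ms))
    growth_every = max(int(round(dt_growth_s * 1000.0 / dt_ms)), 1)
    max_spikes = int(max_spike_rate_hz * n * duration_s) + 1000
    spk_t = np.empty(max_spikes, dtype=np.int64)
    spk_id = np.empty(max_spikes, dtype=np.int64)
    if I_ext is None:
        I_ext = np.zeros(n)
    if growth is None:
        nu = xi = zeta = omega = np.zeros((n, 3))
        z = np.zeros((n, 3)) if z is None else z
        growth_on = False
    else:
        nu, xi, zeta, omega = growth
        growth_on = True
        if z is None:
            raise ValueError("growth enabled but no element-count array given")
    ip = istdp or IstdpParams()
    n_spikes, overflow = _simulate(
        n_steps,
        dt_ms,
        state.V, state.g_exc, state.g_inh, state.ca, state.ref_left, state.x,
        state.rng_state,
        np.ascontiguousarray(is_inh),
        np.ascontiguousarray(drive_on),
        np.ascontiguousarray(g_ext, dtype=np.float64),
        rate_ext_hz * dt_ms * 1e-3,
        np.ascontiguousarray(I_ext, dtype=np.float64),
        indptr, tgt, syn_g,
        ie_indptr, ie_syn, ie_src,
        params.C, params.g_L, params.E_L, params.E_exc, params.E_inh,
        params.V_th, params.V_reset, int(round(params.t_ref / dt_ms)),
        np.exp(-dt_ms / params.tau_exc),
        np.exp(-dt_ms / params.tau_inh),
        np.exp(-dt_ms / (params.tau_ca * 1000.0)),
        np.exp(-dt_ms / (istdp.tau_stdp if istdp else 20.0)),
        params.beta_ca,
        istdp is not None,
        (ip.eta * ip.g_unit) if istdp else 0.0,
        ip.alpha,
        growth_on, growth_every, dt_growth_s,
        z, nu, xi, zeta, omega,
        spk_t, spk_id,
    )
    times_ms = spk_t[:n_spikes] * dt_ms
    return spk_id[:n_spikes].copy(), times_ms, overflow
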