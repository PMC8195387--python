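"""Experiment orchestration: balancing, lesioning, growth-regime batteries
and the isolated single-neuron homeostasis experiment.

A network experiment runs in two phases. During set-up the freshly wired
network is balanced to its low-rate asynchronous-irregular state by
inhibitory STDP alone; at ``t1`` each neuron's optimal activity ``psi`` is
recorded as its current calcium value, growth curves are instantiated
against it, and structural plasticity switches on so the network can be
verified to stay balanced under both mechanisms. At ``t2`` the external
Poisson drive is disconnected from the lesion projection zone (LPZ) and the
network reorganises until ``t_end``.

Axonal growth regimes G0-G5 select where (relative to ``psi``) excitatory
and inhibitory axonal elements sprout; the reference regime G2 — excitatory
axons sprout above the optimum, inhibitory axons below it — is the only one
that reproduces the experimentally observed course of repair.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import AiCriterion, SpikeRaster, is_ai_state, isi_cv, population_rate_sd
from .builder import Connectome, Layout, classify_regions, place_neurons, wire_initial
from .config import ExperimentConfig, MechanismToggles, PhaseSchedule
from .network import Network
from .neurons import KernelState, NeuronParams, simulate_interval
from .plasticity import UpdateConfig

__all__ = [
    "REGIMES",
    "GrowthTable",
    "make_regime_curves",
    "build_network",
    "run_balance_phase",
    "run_lesion_experiment",
    "LesionArtifacts",
    "SingleNeuronConfig",
    "SingleNeuronResult",
    "run_single_neuron_experiment",
]

# Sprouting windows as (eta, epsilon) in multiples of psi. "above": elements
# sprout when activity exceeds the optimum; "below": when it falls short;
# "straddle": peak sprouting exactly at the optimum.
_WINDOWS = {"above": (1.0, 1.75), "below": (0.25, 1.0), "straddle": (0.25, 1.75)}


@dataclass(frozen=True)
class PoolSpec:
    """One growth curve, positioned relative to the neuron's optimum."""

    nu_per_s: float
    omega: float
    window: str  # "above" | "below" | "straddle" | "off" | "flat"


@dataclass(frozen=True)
class GrowthTable:
    """Growth-rule parameters per population and element pool.

    The published scaling factors are quoted per 0.1 s growth step; here they
    are stored per second. The dendritic (post-synaptic) rules are the
    reference configuration — excitatory dendritic elements sprout below the
    optimum (stable fixed point at epsilon = psi), inhibitory ones above it
    (stable fixed point at eta = psi).
    """

    e_axonal: PoolSpec = PoolSpec(1.5e-2, 1e-2, "above")
    i_axonal: PoolSpec = PoolSpec(0.3, 4e-4, "below")
    e_post_e: PoolSpec = PoolSpec(3e-4, 0.4, "below")
    e_post_i: PoolSpec = PoolSpec(3e-3, 4e-2, "above")
    i_post_e: PoolSpec = PoolSpec(3e-4, 0.4, "below")
    i_post_i: PoolSpec = PoolSpec(3e-4, 0.4, "above")


# Axonal-regime battery: window overrides for (excitatory, inhibitory) axons.
REGIMES = {
    "G0": ("off", "off"),
    "G0p": ("flat", "flat"),
    "G1": ("above", "above"),
    "G2": ("above", "below"),
    "G3": ("below", "above"),
    "G4": ("straddle", "straddle"),
    "G5": ("below", "below"),
}


def _curve_params(spec: PoolSpec, psi: np.ndarray, accel: float):
    """Per-neuron (nu, xi, zeta, omega) arrays for one pool spec."""
    n = len(psi)
    nu = np.full(n, spec.nu_per_s * accel)
    if spec.window == "off":
        return np.zeros(n), np.zeros(n), np.ones(n), np.ones(n)
    if spec.window == "flat":
        # constant sprouting at nu irrespective of activity: a Gaussian
        # window vastly wider than any attainable calcium value
        return nu, np.zeros(n), np.full(n, 1e15), np.ones(n)
    eta_f, eps_f = _WINDOWS[spec.window]
    eta, eps = eta_f * psi, eps_f * psi
    xi = 0.5 * (eta + eps)
    zeta = (eps - eta) / (2.0 * np.sqrt(-np.log(spec.omega / 2.0)))
    return nu, xi, zeta, np.full(n, spec.omega)


def make_regime_curves(
    regime: str,
    psi: np.ndarray,
    is_inh: np.ndarray,
    *,
    table: GrowthTable = GrowthTable(),
    accel: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Growth-curve parameter arrays (each (N, 3)) for a regime tag.

    Columns are the element pools: axonal, dendritic-excitatory,
    dendritic-inhibitory. The regime overrides the axonal windows only; the
    dendritic rules always follow the reference configuration.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown growth regime {regime!r}; know {sorted(REGIMES)}")
    e_win, i_win = REGIMES[regime]
    pools = {
        False: [
            dataclasses.replace(table.e_axonal, window=e_win),
            table.e_post_e,
            table.e_post_i,
        ],
        True: [
            dataclasses.replace(table.i_axonal, window=i_win),
            table.i_post_e,
            table.i_post_i,
        ],
    }
    n = len(psi)
    out = [np.zeros((n, 3)) for _ in range(4)]
    for inh in (False, True):
        idx = np.flatnonzero(is_inh == inh)
        for pool, spec in enumerate(pools[inh]):
            for arr, vals in zip(out, _curve_params(spec, psi[idx], accel)):
                arr[idx, pool] = vals
    return tuple(out)  # type: ignore[return-value]


# --------------------------------------------------------------------- #
# network experiments


def build_network(cfg: ExperimentConfig) -> Network:
    """Place, classify and wire a fresh network from a configuration."""
    ss = np.random.SeedSequence(cfg.seed)
    s_place, s_wire, s_run = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    layout = place_neurons(cfg.scale, s_place, mu_d_e=cfg.mu_d_e, sigma_d=cfg.sigma_d)
    regions = classify_regions(layout)
    conn = wire_initial(
        layout,
        cfg.p,
        g_unit=cfg.g_unit,
        g_sigma=cfg.g_sigma,
        w_e=cfg.w_e,
        w_i=cfg.w_i,
        mu_d_e=cfg.mu_d_e,
        seed=s_wire,
    )
    update_cfg = UpdateConfig(
        interval_s=cfg.update_interval_s,
        p_hat_e=cfg.p_hat_e,
        p_hat_i=cfg.p_hat_i,
        w_e=cfg.w_e,
        w_i=cfg.w_i,
        mu_d_e=cfg.mu_d_e,
        g_unit=cfg.g_unit,
        g_sigma=cfg.g_sigma,
        tau_free=cfg.tau_free,
        dt_growth_s=cfg.dt_growth_s,
    )
    return Network(
        layout=layout,
        regions=regions,
        conn=conn,
        params=cfg.neuron,
        drive=cfg.drive,
        istdp=cfg.effective_istdp(),
        update_cfg=update_cfg,
        dt_ms=cfg.dt_ms,
        seed=s_run,
    )


@dataclass
class BalanceRecord:
    """Steady-state quantities recorded when structural plasticity enables."""

    psi: np.ndarray
    g_ie_mean: float
    g_th: float
    ai_ok: bool
    ai_components: dict
    mean_rate_hz: float


def run_balance_phase(
    net: Network, cfg: ExperimentConfig, *, validate: bool = False
) -> BalanceRecord:
    """Balance by inhibitory STDP until t1, then verify stability to t2.

    At t1 the per-neuron optimal activity ``psi`` is recorded from the
    calcium traces, growth curves are instantiated against it, the immunity
    threshold and the mean for new plastic IE synapses are set to the mean
    learned IE conductance, and structural plasticity switches on (when
    enabled by the toggles) for the t1..t2 stability window.
    """
    sched = cfg.schedule
    # the optimal activity psi is the *time-averaged* calcium over the tail
    # of the balancing phase: a single-time sample would carry the full
    # fluctuation of the trace (sd ~ 1/sqrt(2 r tau_ca)) into a permanent
    # per-neuron growth bias
    psi_window = min(20.0, 0.25 * sched.t1)
    net.run(sched.t1 - psi_window, istdp_enabled=True, structural_enabled=False)
    ca_sum = np.zeros(net.n_neurons)
    n_samples = int(round(psi_window))
    for _ in range(n_samples):
        net.run(1.0, istdp_enabled=True, structural_enabled=False)
        ca_sum += net.state.ca
    psi_avg = ca_sum / n_samples

    raster = net.raster()
    window = (max(sched.t1 - 10.0, 0.0) * 1e3, sched.t1 * 1e3)
    ai_ok, comps = is_ai_state(raster, *window)
    mean_rate = raster.window(*window).n_spikes / net.n_neurons / (
        (window[1] - window[0]) / 1e3
    )

    psi = np.maximum(psi_avg, cfg.psi_floor)
    g_ie = net.mean_ie_conductance()
    if g_ie > 0:
        net.update_cfg.g_th = g_ie
        net.update_cfg.g_ie_new = g_ie
    curves = make_regime_curves(
        cfg.regime, psi, net.layout.is_inh, accel=cfg.growth_accel
    )
    net.enable_growth(psi, curves)
    net.rate_ceiling_hz = max(10.0 * mean_rate, 20.0)

    net.run(
        sched.t2 - sched.t1,
        istdp_enabled=cfg.toggles.istdp_enabled,
        structural_enabled=cfg.toggles.structural_enabled,
        record_every=cfg.record_every,
        validate=validate,
    )
    return BalanceRecord(
        psi=psi, g_ie_mean=g_ie, g_th=net.update_cfg.g_th,
        ai_ok=ai_ok, ai_components=comps, mean_rate_hz=float(mean_rate),
    )


@dataclass
class LesionArtifacts:
    """Everything the repair metrics need from one lesion run."""

    raster: SpikeRaster
    regions: np.ndarray
    schedule: PhaseSchedule
    conn_series: pd.DataFrame
    instability_t_s: float | None
    balance: BalanceRecord
    snapshots: dict[str, Connectome]
    layout: Layout
    immune_deleted: int = 0
    validated: bool = False


def run_lesion_experiment(
    cfg: ExperimentConfig, *, validate: bool = False, net: Network | None = None,
    balance: BalanceRecord | None = None,
) -> LesionArtifacts:
    """The full two-phase protocol: balance, deafferent the LPZ, reorganise.

    A pre-balanced network (with its balance record) may be passed in so
    that mechanism-toggle comparisons share an identical set-up phase.
    Numerical runaway (sustained firing above the configured ceiling) ends
    the run early; the artifacts carry the time of instability so the
    metrics can flag partially evaluable features.
    """
    if net is None:
        net = build_network(cfg)
        balance = run_balance_phase(net, cfg, validate=validate)
    elif balance is None:
        raise ValueError("a pre-balanced network requires its balance record")
    snapshots = {"t2": net.conn.copy()}
    net.deafferent()
    net.istdp = cfg.effective_istdp(cfg.stdp_accel_repair)
    net.run(
        cfg.schedule.t_end - cfg.schedule.t2,
        istdp_enabled=cfg.toggles.istdp_enabled,
        structural_enabled=cfg.toggles.structural_enabled,
        record_every=cfg.record_every,
        validate=validate,
    )
    snapshots["t_end"] = net.conn.copy()
    return LesionArtifacts(
        raster=net.raster(),
        regions=net.regions,
        schedule=cfg.schedule,
        conn_series=net.conn_series(),
        instability_t_s=net.instability_t_s,
        balance=balance,
        snapshots=snapshots,
        layout=net.layout,
        immune_deleted=net.immune_deleted,
        validated=validate,
    )


# --------------------------------------------------------------------- #
# single-neuron experiment


@dataclass
class SingleNeuronConfig:
    """Protocol constants for the isolated-neuron homeostasis experiment.

    The neuron is driven by a constant baseline current to define its
    optimal activity, made to sprout dendritic elements under a reduced
    (sub-optimal) current with the excitatory pool growing four times faster
    than the inhibitory one, and then probed with a sinusoidal current. The
    modulation starts with an activity dip, mirroring the deprivation that
    the dendritic rules are built to counter. Conductances per element are
    the means seen in balanced networks.
    """

    i_base_pa: float = 120.0
    i_growin_frac: float = 0.875
    mod_amp_frac: float = 0.30
    mod_period_s: float = 30.0
    n_cycles: int = 3
    baseline_s: float = 30.0
    growin_s: float = 20.0
    z_post_e_target: float = 40.0
    nu_e_growin: float = 2.0  # elements/s; inhibitory pool grows at 1/4 of this
    g_ee: float = 0.5  # nS per excitatory dendritic element
    g_ie: float = 2.0  # nS per inhibitory dendritic element
    tau_ca: float = 5.0
    dt_ms: float = 0.1
    dt_growth_s: float = 0.1
    seed: int = 0


@dataclass
class SingleNeuronResult:
    t_s: np.ndarray
    ca: np.ndarray
    z_post_e: np.ndarray
    z_post_i: np.ndarray
    dg_e: np.ndarray
    dg_i: np.ndarray
    dg_net: np.ndarray
    psi: float
    init_ratio: float
    corr_ca_dgnet: float


def _single_neuron_chunk(state, params, I, curves, z, duration_s, dt_ms, dt_growth_s):
    empty = np.zeros(0, dtype=np.int64)
    return simulate_interval(
        duration_s,
        dt_ms,
        state,
        params,
        is_inh=np.array([False]),
        drive_on=np.array([False]),
        g_ext=np.zeros(1),
        rate_ext_hz=0.0,
        I_ext=np.array([I]),
        indptr=np.zeros(2, dtype=np.int64),
        tgt=empty,
        syn_g=np.zeros(0),
        ie_indptr=np.zeros(2, dtype=np.int64),
        ie_syn=empty,
        ie_src=empty,
        istdp=None,
        growth=curves,
        z=z,
        dt_growth_s=dt_growth_s,
    )


def run_single_neuron_experiment(cfg: SingleNeuronConfig = SingleNeuronConfig()) -> SingleNeuronResult:
    """Three-stage isolated-neuron protocol probing dendritic homeostasis.

    Stage 1 measures the optimal activity ``psi`` under the baseline
    current. Stage 2 grows in dendritic elements under a sub-optimal current
    with identical growth windows for both polarities and a 4:1 speed ratio,
    reproducing the 4:1 excitatory:inhibitory in-degree of balanced
    networks. Stage 3 restores the reference dendritic growth rules and
    modulates the current sinusoidally; the change in net input conductance
    z_post_e * g_EE - z_post_i * g_IE implied by the element turnover is
    recorded against the calcium deviation from ``psi``.
    """
    params = NeuronParams(tau_ca=cfg.tau_ca)
    state = KernelState.fresh(1, params, cfg.seed)
    z = np.zeros((1, 3))
    off = (np.zeros((1, 3)), np.zeros((1, 3)), np.ones((1, 3)), np.ones((1, 3)))

    # stage 1: baseline activity defines the optimum
    _single_neuron_chunk(state, params, cfg.i_base_pa, off, z,
                         cfg.baseline_s, cfg.dt_ms, cfg.dt_growth_s)
    psi = float(state.ca[0])

    # stage 2: grow in under sub-optimal drive; identical windows, nuE = 4 nuI
    eta, eps, omega = 0.25 * psi, 1.0 * psi, 0.4
    xi = 0.5 * (eta + eps)
    zeta = (eps - eta) / (2.0 * np.sqrt(-np.log(omega / 2.0)))
    nu = np.array([[0.0, cfg.nu_e_growin, cfg.nu_e_growin / 4.0]])
    grow = (
        nu,
        np.full((1, 3), xi),
        np.full((1, 3), zeta),
        np.full((1, 3), omega),
    )
    i_grow = cfg.i_growin_frac * cfg.i_base_pa
    for _ in range(10_000):
        if z[0, 1] >= cfg.z_post_e_target:
            break
        _single_neuron_chunk(state, params, i_grow, grow, z,
                             1.0, cfg.dt_ms, cfg.dt_growth_s)
    else:
        raise RuntimeError(
            "grow-in stage failed to reach the target element count; the "
            "sub-optimal drive has likely left the growth window"
        )
    init_ratio = float(z[0, 1] / z[0, 2])
    z0_e, z0_i = z[0, 1], z[0, 2]

    # stage 3: restore baseline and the reference dendritic rules, then probe
    _single_neuron_chunk(state, params, cfg.i_base_pa, off, z,
                         cfg.baseline_s, cfg.dt_ms, cfg.dt_growth_s)
    psi = float(state.ca[0])
    table = GrowthTable()
    ref = make_regime_curves(
        "G0", np.array([psi]), np.array([False]), table=table, accel=1.0
    )
    # dendritic pools only; scale the published rates so turnover is visible
    # within a few modulation cycles
    nu_scale = 1000.0
    ref[0][0, 1] = table.e_post_e.nu_per_s * nu_scale
    ref[0][0, 2] = table.e_post_i.nu_per_s * nu_scale

    t_rec, ca_rec, ze_rec, zi_rec = [], [], [], []
    total = cfg.n_cycles * cfg.mod_period_s
    t = 0.0
    while t < total - 1e-9:
        # activity dip first: I = base - A sin(2 pi t / P)
        i_mod = cfg.i_base_pa * (
            1.0 - cfg.mod_amp_frac * np.sin(2.0 * np.pi * (t + 0.5) / cfg.mod_period_s)
        )
        _single_neuron_chunk(state, params, float(i_mod), ref, z,
                             1.0, cfg.dt_ms, cfg.dt_growth_s)
        t += 1.0
        t_rec.append(t)
        ca_rec.append(state.ca[0])
        ze_rec.append(z[0, 1])
        zi_rec.append(z[0, 2])

    ca_arr = np.array(ca_rec)
    ze, zi = np.array(ze_rec), np.array(zi_rec)
    dg_e = (ze - z0_e) * cfg.g_ee
    dg_i = (zi - z0_i) * cfg.g_ie
    dg_net = dg_e - dg_i
    corr = float(np.corrcoef(ca_arr - psi, dg_net)[0, 1])
    return SingleNeuronResult(
        t_s=np.array(t_rec), ca=ca_arr, z_post_e=ze, z_post_i=zi,
        dg_e=dg_e, dg_i=dg_i, dg_net=dg_net,
        psi=psi, init_ratio=init_ratio, corr_ca_dgnet=corr,
    )
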