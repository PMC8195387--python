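"""Run configuration, fixture generation, serialisation and manifests.

A single :class:`ExperimentConfig` gathers every model parameter with the
full-scale defaults (8000 + 2000 neurons, 0.02 sparsity, the published
neuron, synapse and growth constants). :func:`make_fixture` produces a
scaled-down configuration suitable for desk runs: neuron counts shrink while
the E:I ratio, sparsity, region fractions and per-neuron parameters are
preserved; recurrent unit conductances are scaled by 1/scale so each
neuron's total synaptic input matches the full-scale network, and the plasticity
clocks (STDP learning rate, growth scaling factors, calcium time constant,
phase schedule) are compressed so the same sequence of network states plays
out within minutes instead of hours.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import yaml

from .neurons import ExternalDrive, IstdpParams, NeuronParams

__all__ = [
    "PhaseSchedule",
    "MechanismToggles",
    "ExperimentConfig",
    "load_config",
    "save_config",
    "make_fixture",
    "write_run_manifest",
]


@dataclass(frozen=True)
class PhaseSchedule:
    """Phase boundaries in seconds of simulated time: inhibitory-STDP-only
    balancing until ``t1``, both homeostatic mechanisms until the lesion at
    ``t2``, then reorganisation until ``t_end``."""

    t1: float = 1500.0
    t2: float = 2000.0
    t_end: float = 18_000.0

    def __post_init__(self) -> None:
        if not 0 < self.t1 < self.t2 < self.t_end:
            raise ValueError("require 0 < t1 < t2 < t_end")


@dataclass(frozen=True)
class MechanismToggles:
    """Which homeostatic mechanisms act after the balancing phase.

    The balancing phase itself always runs with inhibitory STDP on; the
    toggles select the post-balance configuration (synaptic-only,
    structural-only, or both)."""

    istdp_enabled: bool = True
    structural_enabled: bool = True


@dataclass
class ExperimentConfig:
    """Complete parameter set for a network experiment."""

    scale: float = 1.0
    seed: int = 0
    # geometry and wiring
    p: float = 0.02
    mu_d_e: float = 150.0
    sigma_d: float = 15.0
    g_unit: float = 0.5
    g_sigma: float = 0.1
    # model constants
    neuron: NeuronParams = field(default_factory=NeuronParams)
    drive: ExternalDrive = field(default_factory=ExternalDrive)
    istdp: IstdpParams = field(default_factory=IstdpParams)
    # structural plasticity
    update_interval_s: float = 1.0
    dt_growth_s: float = 0.1
    tau_free: float = 0.01
    p_hat_e: float = 0.8
    p_hat_i: float = 0.3
    w_e: float = 8.0
    w_i: float = 24.0
    regime: str = "G2"
    # protocol
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)
    toggles: MechanismToggles = field(default_factory=MechanismToggles)
    dt_ms: float = 0.1
    # desk-scale accelerations (1.0 = published clocks). ``stdp_accel``
    # applies to the set-up phases only; after the lesion the synaptic
    # learning rate returns to ``stdp_accel_repair`` times the published
    # value so that activity deviations persist long enough for the (much
    # slower) calcium trace and growth rules to register them.
    stdp_accel: float = 1.0
    stdp_accel_repair: float = 1.0
    growth_accel: float = 1.0
    psi_floor: float = 1e-3
    record_every: int = 5

    def effective_istdp(self, accel: float | None = None) -> IstdpParams:
        if accel is None:
            accel = self.stdp_accel
        return dataclasses.replace(
            self.istdp, eta=self.istdp.eta * accel, g_unit=self.g_unit
        )


def _from_dict(cls, data: dict, path: str = ""):
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise KeyError(f"unknown configuration key {path + key!r}")
        target = _FIELD_TYPES.get((cls, key))
        if target is not None and isinstance(value, dict):
            kwargs[key] = _from_dict(target, value, path=f"{path}{key}.")
        else:
            kwargs[key] = value
    return cls(**kwargs)


_FIELD_TYPES = {
    (ExperimentConfig, "neuron"): NeuronParams,
    (ExperimentConfig, "drive"): ExternalDrive,
    (ExperimentConfig, "istdp"): IstdpParams,
    (ExperimentConfig, "schedule"): PhaseSchedule,
    (ExperimentConfig, "toggles"): MechanismToggles,
}


def load_config(path) -> ExperimentConfig:
    """Load a YAML (or JSON) configuration; unspecified keys take the
    full-scale defaults and unknown keys are rejected by name."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration root must be a mapping")
    return _from_dict(ExperimentConfig, data)


def _as_dict(obj):
    if is_dataclass(obj):
        return {f.name: _as_dict(getattr(obj, f.name)) for f in fields(obj)}
    return obj


def save_config(cfg: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_as_dict(cfg), sort_keys=False))


def make_fixture(scale: float, seed: int = 0, *, t_repair_s: float = 800.0) -> ExperimentConfig:
    """Desk-scale study conditions: the full model, compressed in size and time.

    ``scale`` multiplies the neuron count (0.2 gives 1600 E + 400 I).
    Recurrent conductances are strengthened by ``scale ** -0.75``, between
    mean-input-preserving (1/scale) and fluctuation-preserving (1/sqrt
    (scale)) downscaling: at this exponent the reduced network still
    satisfies the asynchronous-irregular criterion (irregularity above 1,
    population-rate SD under 5 Hz, pairwise correlations ~0.02) at rates
    near the synaptic-plasticity target. Plasticity clocks are compressed:
    STDP learning is 10x faster (the balancing phase shrinks from 1500 s to
    80 s), neurite growth 50x faster (the repair phase from 16,000 s to
    ``t_repair_s``), and the calcium averaging window shrinks from 50 s to
    10 s so the activity estimate can track the compressed schedule.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    n_e = 8000 * scale
    if abs(n_e - round(n_e)) > 1e-9 or round(n_e) % 4:
        nearest = 4 * max(round(n_e / 4), 1) / 8000
        raise ValueError(
            f"scale {scale} yields {n_e:.2f} excitatory neurons; nearest feasible "
            f"scale is {nearest}"
        )
    g_unit = 0.5 * scale**-0.75
    growth_accel = 50.0
    # the free-element decay clock compresses with the growth clock, so the
    # standing crop of unpaired elements (growth rate / decay rate) matches
    # the full-clock model instead of inflating 50-fold
    tau_free = 1.0 - (1.0 - 0.01) ** growth_accel
    # spatial kernels shrink with the torus's linear size so the reach of
    # excitatory/inhibitory projections relative to the lesion zone matches
    # the full-scale geometry
    k = float(np.sqrt(scale))
    return ExperimentConfig(
        scale=scale,
        seed=seed,
        g_unit=g_unit,
        g_sigma=0.1 * (g_unit / 0.5),
        w_e=8.0 * k,
        w_i=24.0 * k,
        tau_free=tau_free,
        # the published calcium clock: its relative fluctuation 1/sqrt(2 r
        # tau_Ca) must stay within the growth windows' flat tails, or the
        # accelerated growth rules turn trace noise into phantom synapses
        neuron=NeuronParams(tau_ca=50.0),
        schedule=PhaseSchedule(t1=220.0, t2=240.0, t_end=240.0 + t_repair_s),
        stdp_accel=10.0,
        stdp_accel_repair=1.0,
        growth_accel=growth_accel,
    )


def config_hash(cfg: ExperimentConfig) -> str:
    return hashlib.sha256(
        json.dumps(_as_dict(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]


def write_run_manifest(cfg: ExperimentConfig, path, *, outputs: dict | None = None,
                       notes: dict | None = None) -> dict:
    """Record everything needed to reproduce a run: config (with hash),
    seed, phase boundaries, acceleration factors and the output files."""
    manifest = {
        "config": _as_dict(cfg),
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "scale": cfg.scale,
        "full_scale": cfg.scale == 1.0 and cfg.stdp_accel == 1.0 and cfg.growth_accel == 1.0,
        "phases": {"t1_s": cfg.schedule.t1, "t2_s": cfg.schedule.t2,
                   "t_end_s": cfg.schedule.t_end},
        "accelerations": {"stdp": cfg.stdp_accel, "growth": cfg.growth_accel},
        "outputs": outputs or {},
    }
    if notes:
        manifest["notes"] = notes
    Path(path).write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
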