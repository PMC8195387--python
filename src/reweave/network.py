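"""Run-loop glue: couples the spiking kernel, the synapse table and the
structural-plasticity engine into a steppable network object.

The membrane dynamics advance in fine steps (default 0.1 ms) inside the
compiled kernel; the network surfaces between kernel calls once per
connectivity-update interval (default 1 s of simulated time) to apply
structural updates, collect spikes and record connectivity summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import SpikeRaster
from .builder import Connectome, Layout
from .neurons import ExternalDrive, IstdpParams, KernelState, NeuronParams, simulate_interval
from .plasticity import BudgetArrays, UpdateConfig, structural_update

__all__ = ["Network"]


def _build_csr(conn: Connectome, is_inh: np.ndarray):
    """Source-major CSR of the synapse table plus an incoming-IE lookup.

    Returns (indptr, tgt, syn_g, order, ie_indptr, ie_syn, ie_src); syn_g is
    a copy in CSR order — the caller writes it back through ``order`` after
    the kernel may have changed plastic conductances.
    """
    n = conn.n_neurons
    order = np.argsort(conn.pre, kind="stable")
    indptr = np.concatenate(
        [[0], np.cumsum(np.bincount(conn.pre, minlength=n))]
    ).astype(np.int64)
    tgt = conn.post[order].astype(np.int64)
    syn_g = conn.g[order].astype(np.float64)
    src = conn.pre[order]
    ie_mask = is_inh[src] & ~is_inh[tgt]
    ie_pos = np.flatnonzero(ie_mask)
    by_tgt = ie_pos[np.argsort(tgt[ie_pos], kind="stable")]
    ie_indptr = np.concatenate(
        [[0], np.cumsum(np.bincount(tgt[ie_pos], minlength=n))]
    ).astype(np.int64)
    return indptr, tgt, syn_g, order, ie_indptr, by_tgt.astype(np.int64), src[by_tgt].astype(np.int64)


@dataclass
class Network:
    """A spatial spiking network with optional structural plasticity."""

    layout: Layout
    regions: np.ndarray
    conn: Connectome
    params: NeuronParams
    drive: ExternalDrive
    istdp: IstdpParams
    update_cfg: UpdateConfig
    dt_ms: float = 0.1
    seed: int = 0

    state: KernelState = field(init=False)
    drive_on: np.ndarray = field(init=False)
    g_ext: np.ndarray = field(init=False)
    budgets: BudgetArrays | None = field(default=None, init=False)
    psi: np.ndarray | None = field(default=None, init=False)
    t_s: float = field(default=0.0, init=False)
    deafferented: bool = field(default=False, init=False)
    instability_t_s: float | None = field(default=None, init=False)
    rate_ceiling_hz: float = field(default=200.0, init=False)
    _ceiling_breaches: int = field(default=0, init=False)

    _spike_ids: list = field(default_factory=list, init=False)
    _spike_times: list = field(default_factory=list, init=False)
    conn_records: list = field(default_factory=list, init=False)
    immune_deleted: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        n = self.layout.n_neurons
        ss = np.random.SeedSequence(self.seed)
        kid, pid = ss.spawn(2)
        self.state = KernelState.fresh(n, self.params, kid.generate_state(1)[0])
        self.plasticity_rng = np.random.default_rng(pid)
        self.drive_on = np.ones(n, dtype=bool)
        self.g_ext = np.where(self.layout.is_inh, self.drive.g_ext_i, self.drive.g_ext_e)

    # ------------------------------------------------------------------ #

    @property
    def n_neurons(self) -> int:
        return self.layout.n_neurons

    def raster(self) -> SpikeRaster:
        ids = np.concatenate(self._spike_ids) if self._spike_ids else np.empty(0, np.int64)
        t = np.concatenate(self._spike_times) if self._spike_times else np.empty(0, float)
        return SpikeRaster(ids, t, self.n_neurons)

    def conn_series(self) -> pd.DataFrame:
        cols = ["t_s", "n_total", "e_out_to_lpzc", "i_in_lpzc", "i_lpz_to_out"]
        return pd.DataFrame(self.conn_records, columns=cols)

    def enable_growth(self, psi: np.ndarray, curves, *, reset_elements: bool = True) -> None:
        """Instantiate element pools against per-neuron optimal activities."""
        self.psi = psi
        if self.budgets is None or reset_elements:
            self.budgets = BudgetArrays.from_connectome(self.conn, curves)
        else:
            self.budgets.curves = curves

    def deafferent(self) -> None:
        """Permanently disconnect external drive from LPZ neurons (both
        populations, centre and inner border)."""
        if self.deafferented:
            raise RuntimeError("network is already deafferented")
        self.drive_on[self.regions <= 1] = False
        self.deafferented = True

    # ------------------------------------------------------------------ #

    def run(
        self,
        duration_s: float,
        *,
        istdp_enabled: bool = True,
        structural_enabled: bool = False,
        record_every: int = 1,
        validate: bool = False,
    ) -> bool:
        """Advance the network; returns False if instability aborted the run.

        ``record_every`` sets the cadence (in update intervals) of the
        region-resolved connectivity records used by the repair metrics.
        """
        interval = self.update_cfg.interval_s
        n_chunks = int(round(duration_s / interval))
        csr = _build_csr(self.conn, self.layout.is_inh)
        for chunk in range(n_chunks):
            indptr, tgt, syn_g, order, ie_indptr, ie_syn, ie_src = csr
            growth = None
            z = None
            if structural_enabled:
                if self.budgets is None:
                    raise RuntimeError("structural plasticity enabled before growth curves set")
                growth = self.budgets.curves
                z = self.budgets.z
            ids, times, overflow = simulate_interval(
                interval,
                self.dt_ms,
                self.state,
                self.params,
                is_inh=self.layout.is_inh,
                drive_on=self.drive_on,
                g_ext=self.g_ext,
                rate_ext_hz=self.drive.rate,
                indptr=indptr,
                tgt=tgt,
                syn_g=syn_g,
                ie_indptr=ie_indptr,
                ie_syn=ie_syn,
                ie_src=ie_src,
                istdp=self.istdp if istdp_enabled else None,
                growth=growth,
                z=z,
                dt_growth_s=self.update_cfg.dt_growth_s,
            )
            self._spike_ids.append(ids)
            self._spike_times.append(times + self.t_s * 1000.0)
            self.conn.g[order] = syn_g
            self.t_s += interval
            mean_rate = len(ids) / (self.n_neurons * interval)
            if overflow or self._breaches_ceiling(mean_rate):
                self.instability_t_s = self.t_s
                return False
            if structural_enabled:
                stats = structural_update(
                    self.conn, self.budgets, self.layout, self.update_cfg,
                    self.plasticity_rng,
                )
                self.immune_deleted += stats["immune_deleted"]
                if validate:
                    self.budgets.validate(self.conn)
                if chunk % record_every == 0 or chunk == n_chunks - 1:
                    self._record_connectivity()
                csr = _build_csr(self.conn, self.layout.is_inh)
        return True

    def _breaches_ceiling(self, mean_rate_hz: float) -> bool:
        # sustained (10 consecutive intervals) firing above the ceiling
        if mean_rate_hz > self.rate_ceiling_hz:
            self._ceiling_breaches += 1
        else:
            self._ceiling_breaches = 0
        return self._ceiling_breaches >= 10

    def _record_connectivity(self) -> None:
        conn, reg = self.conn, self.regions
        exc = conn.cls <= 1
        in_lpzc = reg[conn.post] == 0
        from_outside = reg[conn.pre] >= 2
        from_lpz = reg[conn.pre] <= 1
        to_outside = reg[conn.post] >= 2
        self.conn_records.append(
            {
                "t_s": self.t_s,
                "n_total": conn.n_synapses,
                "e_out_to_lpzc": int(np.count_nonzero(exc & from_outside & in_lpzc)),
                "i_in_lpzc": int(np.count_nonzero(~exc & in_lpzc)),
                "i_lpz_to_out": int(np.count_nonzero(~exc & from_lpz & to_outside)),
            }
        )

    # ------------------------------------------------------------------ #

    def mean_ie_conductance(self) -> float:
        ie = self.conn.cls == 2
        return float(self.conn.g[ie].mean()) if ie.any() else 0.0
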