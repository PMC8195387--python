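"""Spike-train and connectivity analysis: rate maps, irregularity and
synchrony measures, the asynchronous-irregular (AI) state criterion, and
region-resolved connectivity summaries.

The AI criterion follows the convention for balanced cortical network
models: mean inter-spike-interval coefficient of variation above 1 (irregular
single-neuron firing) together with a population-rate standard deviation
below 5 Hz (no strong population-wide fluctuations). Mean pairwise
cross-correlation of binned spike trains below 0.1 is used as an additional
asynchrony measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .builder import REGION_NAMES, SYNAPSE_CLASSES

__all__ = [
    "SpikeRaster",
    "AiCriterion",
    "rate_map",
    "mean_rate",
    "isi_cv",
    "pairwise_cc",
    "population_rate_sd",
    "is_ai_state",
    "region_connectivity_summary",
    "repair_feature_checklist",
    "ChecklistConfig",
]


@dataclass
class SpikeRaster:
    """Spike events as parallel (neuron id, time in ms) arrays."""

    ids: np.ndarray
    times_ms: np.ndarray
    n_neurons: int

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.times_ms = np.asarray(self.times_ms, dtype=float)

    @property
    def n_spikes(self) -> int:
        return len(self.ids)

    def window(self, t_start_ms: float, t_end_ms: float) -> "SpikeRaster":
        m = (self.times_ms >= t_start_ms) & (self.times_ms < t_end_ms)
        return SpikeRaster(self.ids[m], self.times_ms[m], self.n_neurons)

    def subset(self, neuron_ids: np.ndarray) -> "SpikeRaster":
        m = np.isin(self.ids, neuron_ids)
        return SpikeRaster(self.ids[m], self.times_ms[m], self.n_neurons)

    def to_gdf(self, path) -> None:
        """Write the raster as tab-separated "neuron_id<TAB>time_ms" records."""
        order = np.lexsort((self.ids, self.times_ms))
        pd.DataFrame(
            {"neuron_id": self.ids[order], "time_ms": self.times_ms[order]}
        ).to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_gdf(cls, path, n_neurons: int) -> "SpikeRaster":
        df = pd.read_csv(path, sep="\t", header=None, names=["neuron_id", "time_ms"])
        return cls(df["neuron_id"].to_numpy(np.int64), df["time_ms"].to_numpy(float), n_neurons)


@dataclass(frozen=True)
class AiCriterion:
    """Thresholds and sampling rule for the AI-state test."""

    isi_cv_threshold: float = 1.0  # strict >
    rate_sd_threshold: float = 5.0  # Hz, strict <
    cc_reference: float = 0.1
    cc_bin_ms: float = 5.0
    sample_floor: int = 800
    sample_fraction: float = 0.10

    def sample_size(self, n: int) -> int:
        if n <= self.sample_floor:
            return n
        return max(self.sample_floor, int(self.sample_fraction * n))


def rate_map(
    raster: SpikeRaster,
    t_start_ms: float,
    t_end_ms: float,
    window_ms: float = 2500.0,
    step_ms: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window firing rates per neuron.

    Returns ``(t_centres_ms, rates)`` where rates has shape
    (n_neurons, n_windows) in Hz. Windows are aligned to ``t_start_ms`` and
    only full windows inside the interval are reported.
    """
    n_steps_per_window = int(round(window_ms / step_ms))
    edges = np.arange(t_start_ms, t_end_ms + 0.5 * step_ms, step_ms)
    if len(edges) - 1 < n_steps_per_window:
        raise ValueError("interval shorter than one window")
    counts = np.zeros((raster.n_neurons, len(edges) - 1))
    w = raster.window(t_start_ms, edges[-1])
    bin_idx = np.floor((w.times_ms - t_start_ms) / step_ms).astype(int)
    np.add.at(counts, (w.ids, np.clip(bin_idx, 0, counts.shape[1] - 1)), 1.0)
    kernel_sum = np.cumsum(counts, axis=1)
    pad = np.zeros((raster.n_neurons, 1))
    kernel_sum = np.hstack([pad, kernel_sum])
    sums = kernel_sum[:, n_steps_per_window:] - kernel_sum[:, :-n_steps_per_window]
    rates = sums / (window_ms / 1000.0)
    centres = edges[:-1][n_steps_per_window - 1 :] + step_ms - window_ms / 2.0
    return centres, rates


def mean_rate(raster: SpikeRaster, t_start_ms: float, t_end_ms: float,
              neuron_ids: np.ndarray | None = None) -> float:
    """Mean firing rate in Hz over the interval, per neuron in the set."""
    w = raster.window(t_start_ms, t_end_ms)
    if neuron_ids is None:
        n = raster.n_neurons
        count = w.n_spikes
    else:
        neuron_ids = np.asarray(neuron_ids)
        n = len(neuron_ids)
        count = int(np.isin(w.ids, neuron_ids).sum())
    dur_s = (t_end_ms - t_start_ms) / 1000.0
    return count / (n * dur_s) if n else float("nan")


def isi_cv(raster: SpikeRaster, neuron_ids: np.ndarray | None = None) -> float:
    """Mean coefficient of variation of inter-spike intervals.

    Neurons with fewer than two intervals are excluded; returns NaN when no
    neuron qualifies (the measure is undefined in the absence of spikes).
    """
    ids = raster.ids
    times = raster.times_ms
    if neuron_ids is not None:
        m = np.isin(ids, np.asarray(neuron_ids))
        ids, times = ids[m], times[m]
    if len(ids) == 0:
        return float("nan")
    order = np.lexsort((times, ids))
    ids, times = ids[order], times[order]
    cvs = []
    for start, stop in _runs(ids):
        if stop - start < 3:
            continue
        isi = np.diff(times[start:stop])
        mu = isi.mean()
        if mu > 0:
            cvs.append(isi.std() / mu)
    return float(np.mean(cvs)) if cvs else float("nan")


def _runs(sorted_ids: np.ndarray):
    """Yield (start, stop) slices of equal consecutive values."""
    boundaries = np.flatnonzero(np.diff(sorted_ids)) + 1
    edges = np.concatenate([[0], boundaries, [len(sorted_ids)]])
    for i in range(len(edges) - 1):
        yield edges[i], edges[i + 1]


def _binned_counts(raster: SpikeRaster, neuron_ids: np.ndarray,
                   t_start_ms: float, t_end_ms: float, bin_ms: float) -> np.ndarray:
    n_bins = int(np.floor((t_end_ms - t_start_ms) / bin_ms))
    w = raster.window(t_start_ms, t_start_ms + n_bins * bin_ms)
    remap = -np.ones(raster.n_neurons, dtype=np.int64)
    remap[neuron_ids] = np.arange(len(neuron_ids))
    rows = remap[w.ids]
    keep = rows >= 0
    cols = np.floor((w.times_ms[keep] - t_start_ms) / bin_ms).astype(int)
    counts = np.zeros((len(neuron_ids), n_bins))
    np.add.at(counts, (rows[keep], np.clip(cols, 0, n_bins - 1)), 1.0)
    return counts


def pairwise_cc(
    raster: SpikeRaster,
    t_start_ms: float,
    t_end_ms: float,
    *,
    bin_ms: float = 5.0,
    criterion: AiCriterion = AiCriterion(),
    neuron_ids: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> float:
    """Mean Pearson correlation between binned spike-count trains.

    Neurons are sampled according to the criterion's rule (all if the
    population is small, otherwise the larger of 800 and 10%); trains with
    zero variance are excluded from pairing. Returns NaN if fewer than two
    trains qualify.
    """
    rng = np.random.default_rng(seed)
    if neuron_ids is None:
        neuron_ids = np.unique(raster.ids)
    neuron_ids = np.asarray(neuron_ids)
    k = criterion.sample_size(len(neuron_ids))
    if k < len(neuron_ids):
        neuron_ids = rng.choice(neuron_ids, size=k, replace=False)
    counts = _binned_counts(raster, neuron_ids, t_start_ms, t_end_ms, bin_ms)
    counts = counts[counts.std(axis=1) > 0]
    if len(counts) < 2:
        return float("nan")
    corr = np.corrcoef(counts)
    iu = np.triu_indices_from(corr, k=1)
    return float(corr[iu].mean())


def population_rate_sd(
    raster: SpikeRaster, t_start_ms: float, t_end_ms: float, bin_ms: float = 5.0
) -> float:
    """SD (Hz per neuron) of the instantaneous population firing rate.

    The population spike histogram at the synchrony bin width is converted to
    a per-neuron rate, and the standard deviation taken over bins.
    """
    n_bins = int(np.floor((t_end_ms - t_start_ms) / bin_ms))
    w = raster.window(t_start_ms, t_start_ms + n_bins * bin_ms)
    hist = np.bincount(
        np.floor((w.times_ms - t_start_ms) / bin_ms).astype(int), minlength=n_bins
    )[:n_bins]
    rate = hist / raster.n_neurons / (bin_ms / 1000.0)
    return float(rate.std())


def is_ai_state(
    raster: SpikeRaster,
    t_start_ms: float,
    t_end_ms: float,
    criterion: AiCriterion = AiCriterion(),
) -> tuple[bool, dict]:
    """Test the asynchronous-irregular criterion on an analysis window.

    True iff mean ISI CV > 1 and population-rate SD < 5 Hz. The component
    values (including the mean pairwise correlation, reported for reference
    against the 0.1 asynchrony convention) are always returned.
    """
    w = raster.window(t_start_ms, t_end_ms)
    cv = isi_cv(w)
    sd = population_rate_sd(raster, t_start_ms, t_end_ms, criterion.cc_bin_ms)
    components = {"isi_cv": cv, "rate_sd_hz": sd}
    ok = bool(cv > criterion.isi_cv_threshold) and bool(sd < criterion.rate_sd_threshold)
    return ok, components


def region_connectivity_summary(
    conn, regions: np.ndarray, *, by: str = "incoming"
) -> pd.DataFrame:
    """Counts and mean conductances of projections split by region and class.

    ``by="incoming"`` groups synapses by target region and source region
    (dendritic view); ``by="outgoing"`` swaps the roles (axonal view). The
    result has one row per (target_region, source_region, class) present.
    """
    if len(regions) != conn.n_neurons:
        raise ValueError("region labels do not match the connectome's layout")
    df = pd.DataFrame(
        {
            "source_region": np.take(REGION_NAMES, regions[conn.pre]),
            "target_region": np.take(REGION_NAMES, regions[conn.post]),
            "class": np.take(SYNAPSE_CLASSES, conn.cls),
            "g_nS": conn.g,
        }
    )
    keys = (
        ["target_region", "source_region", "class"]
        if by == "incoming"
        else ["source_region", "target_region", "class"]
    )
    out = df.groupby(keys, observed=True)["g_nS"].agg(count="size", mean_g_nS="mean")
    return out.reset_index()


@dataclass(frozen=True)
class ChecklistConfig:
    """Thresholds for the qualitative repair-feature checklist.

    ``recovery_frac`` defines "recovered": a region's sliding mean rate has
    returned to at least this fraction of its pre-lesion value.
    ``normal_band`` bounds "normalised": within this relative band of the
    pre-lesion value. ``disinhibition_frac``: the inhibitory input count to
    the LPZ centre must dip below this fraction of its pre-lesion value.
    """

    recovery_frac: float = 0.5
    normal_band: float = 0.5
    disinhibition_frac: float = 0.9
    stability_tol: float = 0.05
    rate_window_ms: float = 10_000.0
    rate_step_ms: float = 1_000.0


CHECKLIST_ROWS = (
    "initial_stability",
    "lpz_rate_recovery",
    "outside_rate_normalises",
    "final_balanced_state",
    "lpz_b_before_lpz_c",
    "excitatory_ingrowth",
    "inhibitory_outgrowth",
    "transient_disinhibition",
)


def _recovery_time(raster, ids, t2_ms, t_end_ms, target_hz, cfg) -> float | None:
    if len(ids) == 0 or t_end_ms - t2_ms < cfg.rate_window_ms:
        return None
    t, rates = rate_map(
        raster.subset(ids), t2_ms, t_end_ms, cfg.rate_window_ms, cfg.rate_step_ms
    )
    mean_r = rates[ids].mean(axis=0)
    hit = np.flatnonzero(mean_r >= target_hz)
    return float(t[hit[0]]) if len(hit) else None


def repair_feature_checklist(artifacts, cfg: ChecklistConfig = ChecklistConfig()) -> dict:
    """Evaluate the eight experimentally observed repair features on a run.

    ``artifacts`` is the record returned by the lesion experiment: it must
    expose ``raster``, ``regions``, ``schedule`` (with t1/t2/t_end in s),
    ``conn_series`` (per-update DataFrame with columns ``t_s``, ``n_total``,
    ``e_out_to_lpzc``, ``i_in_lpzc``, ``i_lpz_to_out``) and
    ``instability_t_s``. Rows that cannot be evaluated (e.g. the run was
    terminated early, or a prerequisite row failed) are marked ``None``,
    mirroring a "not applicable" entry.
    """
    res: dict[str, bool | None] = {row: None for row in CHECKLIST_ROWS}
    raster = artifacts.raster
    regions = artifacts.regions
    sched = artifacts.schedule
    series = artifacts.conn_series
    t1_ms, t2_ms, tend_ms = sched.t1 * 1e3, sched.t2 * 1e3, sched.t_end * 1e3

    pre = series[(series.t_s >= sched.t1) & (series.t_s <= sched.t2)]
    if len(pre):
        spread = pre.n_total.max() - pre.n_total.min()
        stable_counts = spread <= cfg.stability_tol * pre.n_total.iloc[0]
        no_blowup = artifacts.instability_t_s is None or artifacts.instability_t_s > sched.t2
        res["initial_stability"] = bool(stable_counts and no_blowup)

    lpzc = np.flatnonzero(regions == 0)
    lpzb = np.flatnonzero(regions == 1)
    peri = np.flatnonzero(regions == 2)
    pre_lpzc = mean_rate(raster, t1_ms, t2_ms, lpzc)
    pre_lpzb = mean_rate(raster, t1_ms, t2_ms, lpzb)
    pre_peri = mean_rate(raster, t1_ms, t2_ms, peri)

    complete = artifacts.instability_t_s is None
    final_window = (max(tend_ms - 50_000.0, t2_ms), tend_ms)
    if complete:
        final_lpzc = mean_rate(raster, *final_window, lpzc)
        final_peri = mean_rate(raster, *final_window, peri)
        res["lpz_rate_recovery"] = bool(final_lpzc >= cfg.recovery_frac * pre_lpzc)
        res["outside_rate_normalises"] = bool(
            final_peri <= (1.0 + cfg.normal_band) * pre_peri
        )
        if res["lpz_rate_recovery"]:
            ok, _ = is_ai_state(raster, *final_window)
            res["final_balanced_state"] = ok
            tb = _recovery_time(raster, lpzb, t2_ms, tend_ms,
                                cfg.recovery_frac * pre_lpzb, cfg)
            tc = _recovery_time(raster, lpzc, t2_ms, tend_ms,
                                cfg.recovery_frac * pre_lpzc, cfg)
            if tb is not None and tc is not None:
                res["lpz_b_before_lpz_c"] = bool(tb < tc)

    post = series[series.t_s > sched.t2]
    ref = series[series.t_s <= sched.t2]
    if len(post) and len(ref):
        e_ref = ref.e_out_to_lpzc.iloc[-1]
        i_ref = ref.i_in_lpzc.iloc[-1]
        o_ref = ref.i_lpz_to_out.iloc[-1]
        res["excitatory_ingrowth"] = bool(post.e_out_to_lpzc.iloc[-1] > e_ref)
        res["inhibitory_outgrowth"] = bool(post.i_lpz_to_out.iloc[-1] > o_ref)
        dip = post.i_in_lpzc.min()
        res["transient_disinhibition"] = bool(
            dip < cfg.disinhibition_frac * i_ref and post.i_in_lpzc.iloc[-1] > dip
        )
    return res
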