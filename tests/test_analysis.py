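"""Spike-train metrics, the AI criterion and connectivity summaries."""

import numpy as np
import pandas as pd
import pytest

from reweave.analysis import (
    AiCriterion,
    ChecklistConfig,
    SpikeRaster,
    is_ai_state,
    isi_cv,
    mean_rate,
    pairwise_cc,
    population_rate_sd,
    rate_map,
    region_connectivity_summary,
    repair_feature_checklist,
)
from reweave.builder import Connectome
from reweave.config import PhaseSchedule


def poisson_raster(rng, n_neurons, rate_hz, t_ms):
    counts = rng.poisson(rate_hz * t_ms / 1000.0, size=n_neurons)
    ids = np.repeat(np.arange(n_neurons), counts)
    times = rng.uniform(0, t_ms, size=counts.sum())
    return SpikeRaster(ids, times, n_neurons)


class TestRateMap:
    def test_silent_and_periodic_neurons(self):
        # neuron 0 silent, neuron 1 spikes at exactly 10 Hz
        times = np.arange(0, 10_000, 100.0)
        raster = SpikeRaster(np.ones_like(times, dtype=int), times, 2)
        t, rates = rate_map(raster, 0, 10_000, window_ms=2500, step_ms=100)
        assert np.all(rates[0] == 0.0)
        np.testing.assert_allclose(rates[1], 10.0, atol=0.41)

    def test_integrates_to_spike_count(self, rng):
        raster = poisson_raster(rng, 20, 8.0, 20_000)
        t, rates = rate_map(raster, 0, 20_000, window_ms=1000, step_ms=1000)
        # non-overlapping windows: total rate * window = total count
        assert rates.sum() * 1.0 == pytest.approx(raster.n_spikes, rel=1e-12)

    def test_poisson_mean(self, rng):
        raster = poisson_raster(rng, 100, 10.0, 30_000)
        _, rates = rate_map(raster, 0, 30_000)
        assert rates.mean() == pytest.approx(10.0, rel=0.05)


class TestIsiCv:
    def test_periodic_train_has_zero_cv(self):
        times = np.arange(0, 5000, 50.0)
        raster = SpikeRaster(np.zeros_like(times, dtype=int), times, 1)
        assert isi_cv(raster) == pytest.approx(0.0, abs=1e-12)

    def test_poisson_train_cv_near_one(self, rng):
        times = np.cumsum(rng.exponential(100.0, size=10_000))
        raster = SpikeRaster(np.zeros_like(times, dtype=int), times, 1)
        assert isi_cv(raster) == pytest.approx(1.0, abs=0.05)

    def test_undefined_without_enough_intervals(self):
        raster = SpikeRaster(np.array([0, 1]), np.array([10.0, 20.0]), 2)
        assert np.isnan(isi_cv(raster))


class TestPairwiseCc:
    def test_identical_trains(self):
        times = np.sort(np.random.default_rng(0).uniform(0, 10_000, 500))
        ids = np.concatenate([np.zeros(500, int), np.ones(500, int)])
        raster = SpikeRaster(ids, np.concatenate([times, times]), 2)
        assert pairwise_cc(raster, 0, 10_000) == pytest.approx(1.0)

    def test_independent_trains_uncorrelated(self, rng):
        raster = poisson_raster(rng, 100, 10.0, 100_000)
        assert abs(pairwise_cc(raster, 0, 100_000, seed=0)) < 0.02

    def test_symmetric_under_whole_bin_shift(self, rng):
        raster = poisson_raster(rng, 30, 20.0, 20_000)
        base = pairwise_cc(raster, 0, 20_000, seed=1)
        shifted = SpikeRaster(raster.ids, raster.times_ms + 10.0, raster.n_neurons)
        assert pairwise_cc(shifted, 10.0, 20_010.0, seed=1) == pytest.approx(
            base, abs=1e-9
        )

    @pytest.mark.parametrize(
        "n,expected", [(500, 500), (800, 800), (5000, 800), (10_000, 1000)]
    )
    def test_sampling_rule(self, n, expected):
        assert AiCriterion().sample_size(n) == expected


class TestAiState:
    def _synthetic(self, rng, cv_like, sync):
        n, t_end = 100, 60_000
        ids, times = [], []
        for i in range(n):
            if cv_like == "bursty":
                # gamma ISIs with shape 1/2: CV = sqrt(2), super-Poisson
                t = np.cumsum(rng.gamma(0.5, 200.0, size=700))
            else:
                t = np.arange(0, t_end, 100.0) + rng.uniform(0, 100)
            if sync:
                t = np.round(t / 200.0) * 200.0  # population-wide lockstep
            keep = t < t_end
            ids.append(np.full(keep.sum(), i))
            times.append(t[keep])
        return SpikeRaster(np.concatenate(ids), np.concatenate(times), n)

    def test_async_irregular_accepted(self, rng):
        raster = self._synthetic(rng, "bursty", sync=False)
        ok, comps = is_ai_state(raster, 0, 60_000)
        assert ok and comps["isi_cv"] > 1 and comps["rate_sd_hz"] < 5

    def test_synchronous_raster_rejected(self, rng):
        raster = self._synthetic(rng, "bursty", sync=True)
        ok, comps = is_ai_state(raster, 0, 60_000)
        assert not ok and comps["rate_sd_hz"] >= 5

    def test_regular_raster_rejected(self, rng):
        raster = self._synthetic(rng, "regular", sync=False)
        ok, comps = is_ai_state(raster, 0, 60_000)
        assert not ok and comps["isi_cv"] <= 1

    def test_population_sd_of_silence(self):
        raster = SpikeRaster(np.empty(0, int), np.empty(0), 10)
        assert population_rate_sd(raster, 0, 1000) == 0.0


class TestRegionSummary:
    def test_manual_tally_on_toy_connectome(self):
        # 5 synapses, hand-tallied: regions [0,1,2,3] for neurons 0..3
        regions = np.array([0, 1, 2, 3], dtype=np.int8)
        conn = Connectome(
            pre=np.array([1, 2, 2, 3, 0]),
            post=np.array([0, 0, 1, 0, 3]),
            g=np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
            cls=np.array([0, 0, 2, 2, 0], dtype=np.int8),
            n_neurons=4,
        )
        table = region_connectivity_summary(conn, regions)
        row = table.set_index(["target_region", "source_region", "class"])
        assert row.loc[("LPZ-C", "LPZ-B", "EE"), "count"] == 1
        assert row.loc[("LPZ-C", "other", "IE"), "count"] == 1
        assert row.loc[("LPZ-C", "peri-LPZ", "EE"), "mean_g_nS"] == 2.0
        assert table["count"].sum() == 5

    def test_empty_connectome(self):
        conn = Connectome(
            pre=np.empty(0, int), post=np.empty(0, int),
            g=np.empty(0), cls=np.empty(0, np.int8), n_neurons=3,
        )
        table = region_connectivity_summary(conn, np.zeros(3, np.int8))
        assert len(table) == 0

    def test_label_mismatch_rejected(self, small_connectome):
        with pytest.raises(ValueError):
            region_connectivity_summary(small_connectome, np.zeros(3, np.int8))


class _FakeArtifacts:
    def __init__(self, raster, regions, schedule, series, instability=None):
        self.raster = raster
        self.regions = regions
        self.schedule = schedule
        self.conn_series = series
        self.instability_t_s = instability


def _artifact_fixture(rng, *, recover=True, b_first=True, ingrowth=True, dip=True):
    """Synthetic run artifacts with controllable repair features."""
    n = 200
    regions = np.full(n, 3, dtype=np.int8)
    regions[:20] = 0  # LPZ-C
    regions[20:40] = 1  # LPZ-B
    regions[40:80] = 2
    sched = PhaseSchedule(t1=10.0, t2=30.0, t_end=130.0)
    ids, times = [], []
    for i in range(n):
        pieces = [(0.0, 30_000.0, 5.0)]
        if regions[i] <= 1:
            t_back = 60_000.0 if (regions[i] == 1 and b_first) else 90_000.0
            if not recover:
                t_back = np.inf
            pieces += [(30_000.0, t_back, 0.2), (t_back, 130_000.0, 5.0)]
        else:
            pieces += [(30_000.0, 130_000.0, 5.0)]
        for a, b, r in pieces:
            if not np.isfinite(b - a) or b <= a:
                continue
            k = rng.poisson(r * (b - a) / 1000.0)
            ids.append(np.full(k, i))
            times.append(np.cumsum(rng.exponential(1000.0 / r, size=k)) + a)
    raster = SpikeRaster(np.concatenate(ids), np.concatenate(times), n)
    t = np.arange(10.0, 131.0, 5.0)
    e_in = np.where(t <= 30, 100, 100 + (ingrowth * 2.0) * (t - 30))
    i_in = np.full_like(t, 50.0)
    if dip:
        i_in = np.where((t > 30) & (t < 70), 35.0, 50.0)
    series = pd.DataFrame(
        {
            "t_s": t,
            "n_total": np.full_like(t, 4000.0),
            "e_out_to_lpzc": e_in,
            "i_in_lpzc": i_in,
            "i_lpz_to_out": np.where(t <= 30, 30.0, 45.0),
        }
    )
    return _FakeArtifacts(raster, regions, sched, series)


class TestRepairChecklist:
    def test_full_recovery_pattern(self, rng):
        art = _artifact_fixture(rng)
        res = repair_feature_checklist(art)
        assert res["initial_stability"]
        assert res["lpz_rate_recovery"]
        assert res["outside_rate_normalises"]
        assert res["lpz_b_before_lpz_c"]
        assert res["excitatory_ingrowth"]
        assert res["inhibitory_outgrowth"]
        assert res["transient_disinhibition"]

    def test_no_recovery_marks_dependent_rows_na(self, rng):
        art = _artifact_fixture(rng, recover=False)
        res = repair_feature_checklist(art)
        assert not res["lpz_rate_recovery"]
        assert res["final_balanced_state"] is None
        assert res["lpz_b_before_lpz_c"] is None

    def test_reversed_recovery_order_detected(self, rng):
        art = _artifact_fixture(rng, b_first=False)
        assert repair_feature_checklist(art)["lpz_b_before_lpz_c"] is False

    def test_missing_ingrowth_and_dip_detected(self, rng):
        art = _artifact_fixture(rng, ingrowth=False, dip=False)
        res = repair_feature_checklist(art)
        assert res["excitatory_ingrowth"] is False
        assert res["transient_disinhibition"] is False


def test_gdf_round_trip(tmp_path, rng):
    raster = poisson_raster(rng, 10, 5.0, 1000)
    raster.to_gdf(tmp_path / "spikes.gdf")
    back = SpikeRaster.from_gdf(tmp_path / "spikes.gdf", 10)
    assert back.n_spikes == raster.n_spikes
    assert mean_rate(back, 0, 1000) == pytest.approx(mean_rate(raster, 0, 1000))
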