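"""Structural-plasticity engine: formation, deletion, immunity and the
element-conservation bookkeeping."""

import numpy as np
import pytest

from reweave.builder import Connectome, Layout, classify_regions, wire_initial
from reweave.plasticity import (
    AXONAL,
    POST_E,
    POST_I,
    BudgetArrays,
    UpdateConfig,
    connected_counts,
    deletion_probability,
    formation_probability,
    structural_update,
)


def flat_curves(n):
    return (np.zeros((n, 3)), np.zeros((n, 3)), np.ones((n, 3)), np.ones((n, 3)))


def make_budgets(conn):
    return BudgetArrays.from_connectome(conn, flat_curves(conn.n_neurons))


class TestProbabilities:
    def test_formation_at_zero_distance_is_p_hat(self):
        assert formation_probability(0.0, 0.8, 8.0) == pytest.approx(0.8)
        assert formation_probability(0.0, 0.3, 24.0) == pytest.approx(0.3)

    def test_formation_at_kernel_width(self):
        d = 8.0 * 150.0
        assert formation_probability(d, 0.8, 8.0) == pytest.approx(0.8 / np.e)

    def test_formation_vanishes_at_infinity(self):
        assert formation_probability(1e9, 0.8, 8.0) == pytest.approx(0.0, abs=1e-12)

    def test_deletion_probability_values(self):
        assert deletion_probability(0.0, 1.0) == 1.0
        assert deletion_probability(2.0, 1.0) == pytest.approx(np.exp(-1.0))
        with pytest.raises(ValueError):
            deletion_probability(1.0, 0.0)


def two_neuron_layout(distance=0.0):
    # torus large enough that the test distances are not wrapped
    pos = np.array([[100.0, 100.0], [100.0 + distance, 100.0]])
    return Layout(pos, np.array([False, False]), (10_000.0, 10_000.0))


class TestFormation:
    def test_adjacent_free_pair_forms_one_synapse(self, rng):
        layout = two_neuron_layout()
        conn = Connectome(np.empty(0, np.int64), np.empty(0, np.int64),
                          np.empty(0), np.empty(0, np.int8), 2)
        bud = make_budgets(conn)
        bud.z[0, AXONAL] = bud.z[1, POST_E] = 1.0
        cfg = UpdateConfig(p_hat_e=1.0, tau_free=0.0)
        structural_update(conn, bud, layout, cfg, rng)
        assert conn.n_synapses == 1
        assert (conn.pre[0], conn.post[0]) == (0, 1)
        assert bud.z_connected[0, AXONAL] == 1
        assert bud.z_connected[1, POST_E] == 1
        assert conn.g[0] > 0

    def test_no_autapse_even_with_own_free_elements(self, rng):
        layout = two_neuron_layout()
        conn = Connectome(np.empty(0, np.int64), np.empty(0, np.int64),
                          np.empty(0), np.empty(0, np.int8), 2)
        bud = make_budgets(conn)
        bud.z[0, AXONAL] = bud.z[0, POST_E] = 5.0  # only neuron 0 has elements
        cfg = UpdateConfig(p_hat_e=1.0)
        structural_update(conn, bud, layout, cfg, rng)
        assert conn.n_synapses == 0

    def test_acceptance_rate_follows_spatial_kernel(self, rng):
        """P(accept | distance) matches the Gaussian formation kernel."""
        w, mu = 8.0, 150.0
        distances = np.array([0.0, 600.0, 1200.0, 2400.0])
        accepted = []
        for d in distances:
            layout = two_neuron_layout(d)
            hits = 0
            trials = 400
            for _ in range(trials):
                conn = Connectome(np.empty(0, np.int64), np.empty(0, np.int64),
                                  np.empty(0), np.empty(0, np.int8), 2)
                bud = make_budgets(conn)
                bud.z[0, AXONAL] = bud.z[1, POST_E] = 1.0
                structural_update(conn, bud, layout,
                                  UpdateConfig(p_hat_e=0.8, w_e=w, mu_d_e=mu), rng)
                hits += conn.n_synapses
            accepted.append(hits / trials)
        expected = formation_probability(distances, 0.8, w, mu)
        np.testing.assert_allclose(accepted, expected, atol=0.08)

    def test_formation_capped_by_free_supply(self, rng):
        layout = two_neuron_layout()
        conn = Connectome(np.empty(0, np.int64), np.empty(0, np.int64),
                          np.empty(0), np.empty(0, np.int8), 2)
        bud = make_budgets(conn)
        bud.z[0, AXONAL] = 10.0
        bud.z[1, POST_E] = 3.0
        structural_update(conn, bud, layout, UpdateConfig(p_hat_e=1.0), rng)
        assert conn.n_synapses == 3  # limited by the dendritic side


class TestDeletion:
    def _wired(self, rng, seed=0):
        layout = Layout(
            rng.uniform(0, 1000, size=(40, 2)),
            np.arange(40) >= 32,
            (1000.0, 1000.0),
        )
        conn = wire_initial(layout, 0.1, g_unit=1.0, g_sigma=0.1, seed=seed)
        return layout, conn

    def test_loss_deletes_requested_count(self, rng):
        layout, conn = self._wired(rng)
        bud = make_budgets(conn)
        n0 = conn.n_synapses
        victim = 3
        before = bud.z_connected[victim, AXONAL]
        bud.z[victim, AXONAL] = before - 2.0  # demand two axonal losses
        structural_update(conn, bud, layout, UpdateConfig(), rng)
        assert bud.z_connected[victim, AXONAL] == before - 2
        assert conn.n_synapses == n0 - 2
        bud.validate(conn)

    def test_immune_synapses_never_deleted(self, rng):
        layout, conn = self._wired(rng)
        # make all II/IE synapses strong except one weak candidate per pool
        g_th = 5.0
        inh_src = layout.is_inh[conn.pre]
        conn.g[inh_src] = 10.0
        weak = np.flatnonzero(inh_src)[0]
        conn.g[weak] = 0.5
        bud = make_budgets(conn)
        src = conn.pre[weak]
        bud.z[src, AXONAL] = bud.z_connected[src, AXONAL] - 1.0
        cfg = UpdateConfig(g_th=g_th)
        structural_update(conn, bud, layout, cfg, rng)
        # only the weak synapse was a candidate; the strong ones survived
        assert (conn.g[layout.is_inh[conn.pre]] >= 10.0).all() or conn.n_synapses < 0
        assert not ((conn.pre == src) & (conn.g == 0.5)).any()
        bud.validate(conn)

    def test_all_immune_pool_deletes_nothing(self, rng):
        layout, conn = self._wired(rng)
        inh_src = layout.is_inh[conn.pre]
        conn.g[inh_src] = 10.0
        bud = make_budgets(conn)
        srcs = np.flatnonzero(layout.is_inh)
        bud.z[srcs, AXONAL] = np.maximum(bud.z[srcs, AXONAL] - 3.0, 0)
        n0 = conn.n_synapses
        structural_update(conn, bud, layout, UpdateConfig(g_th=5.0), rng)
        assert conn.n_synapses == n0


class TestConservation:
    def test_quiescent_update_is_identity(self, rng, small_layout, small_connectome):
        conn = small_connectome.copy()
        bud = make_budgets(conn)
        n0 = conn.n_synapses
        stats = structural_update(conn, bud, small_layout, UpdateConfig(), rng)
        assert conn.n_synapses == n0
        assert stats["formed"].sum() == 0 and stats["deleted"].sum() == 0

    def test_class_sums_balance_after_randomised_updates(self, rng, small_layout):
        """Per polarity, axonal connected counts equal dendritic connected
        counts equal the synapse count, after every update."""
        conn = wire_initial(small_layout, 0.02, g_unit=1.0, g_sigma=0.2, seed=3)
        bud = make_budgets(conn)
        cfg = UpdateConfig(g_th=2.0)
        inh = small_layout.is_inh
        for it in range(5):
            bud.z += rng.normal(0.0, 2.0, size=bud.z.shape)
            bud.z = np.maximum(bud.z, 0.0)
            structural_update(conn, bud, small_layout, cfg, rng)
            bud.validate(conn)
            exc_syn = int(np.count_nonzero(conn.cls <= 1))
            inh_syn = conn.n_synapses - exc_syn
            assert bud.z_connected[~inh, AXONAL].sum() == exc_syn
            assert bud.z_connected[inh, AXONAL].sum() == inh_syn
            assert bud.z_connected[:, POST_E].sum() == exc_syn
            assert bud.z_connected[:, POST_I].sum() == inh_syn

    def test_validate_detects_corruption(self, small_layout, small_connectome):
        bud = make_budgets(small_connectome)
        bud.z_connected[0, AXONAL] += 1
        with pytest.raises(RuntimeError, match="bookkeeping"):
            bud.validate(small_connectome)

    def test_connected_counts_match_degree_views(self, small_connectome):
        zc = connected_counts(small_connectome)
        assert (zc[:, AXONAL] == small_connectome.out_degree()).all()
        assert zc.sum() == 2 * small_connectome.n_synapses
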