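"""Structural-plasticity connectivity updates.

At every update interval (1 s of simulated time) the engine:

1. deletes synapses for every element pool whose continuous count ``z`` fell
   below its connected count — uniformly at random for excitatory-class
   pools, weighted by the deletion probability exp(-(g / 2 g_th)^2) for
   inhibitory-class pools, where synapses at or above the immunity threshold
   ``g_th`` are never candidates;
2. harvests free elements (floor(z - z_connected));
3. forms new synapses by pairing free axonal elements with free dendritic
   elements of matching polarity, accepting candidate partners with the
   Gaussian spatial kernel p_hat * exp(-(d / (w * mu_dE))^2);
4. decays the remaining free elements;

and initialises the conductances of new synapses from a Gaussian around the
class mean (for the plastic IE class, around the mean learned conductance
recorded at network balance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .builder import Connectome, Layout

__all__ = [
    "AXONAL",
    "POST_E",
    "POST_I",
    "UpdateConfig",
    "BudgetArrays",
    "formation_probability",
    "deletion_probability",
    "structural_update",
]

# Pool columns of the (N, 3) budget arrays.
AXONAL, POST_E, POST_I = 0, 1, 2


@dataclass
class UpdateConfig:
    """Parameters of the connectivity update."""

    interval_s: float = 1.0
    p_hat_e: float = 0.8
    p_hat_i: float = 0.3
    w_e: float = 8.0
    w_i: float = 24.0
    mu_d_e: float = 150.0
    g_th: float = 1.0  # immunity threshold, recorded at balance
    g_unit: float = 0.5
    g_sigma: float = 0.1
    g_ie_new: float = 0.0  # mean for new IE synapses, recorded at balance
    tau_free: float = 0.01  # per growth step
    dt_growth_s: float = 0.1

    def __post_init__(self) -> None:
        for p in (self.p_hat_e, self.p_hat_i):
            if not 0.0 <= p <= 1.0:
                raise ValueError("formation probabilities must lie in [0, 1]")

    def new_conductance_mean(self, cls: int) -> float:
        return (self.g_unit, self.g_unit, self.g_ie_new, 10.0 * self.g_unit)[cls]


def formation_probability(d, p_hat: float, w: float, mu_d_e: float = 150.0):
    """Probability of forming a synapse across distance ``d`` (um)."""
    return p_hat * np.exp(-((np.asarray(d, dtype=float) / (w * mu_d_e)) ** 2))


def deletion_probability(g, g_th: float):
    """Deletion weight for a synapse of conductance ``g``; immune synapses
    (g >= g_th) are excluded from candidacy before this is applied."""
    if g_th <= 0:
        raise ValueError("g_th must be positive")
    return np.exp(-((np.asarray(g, dtype=float) / (2.0 * g_th)) ** 2))


@dataclass
class BudgetArrays:
    """Per-neuron element pools as (N, 3) arrays: axonal, post-E, post-I.

    A neuron's axonal pool carries the polarity of its population, so
    excitatory neurons never own inhibitory axonal elements and vice versa.
    """

    z: np.ndarray
    z_connected: np.ndarray
    z_free: np.ndarray
    curves: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]  # nu, xi, zeta, omega

    @classmethod
    def from_connectome(cls, conn: Connectome, curves) -> "BudgetArrays":
        """Initialise pools in equilibrium with the existing connectome."""
        zc = connected_counts(conn)
        return cls(
            z=zc.astype(float),
            z_connected=zc.copy(),
            z_free=np.zeros_like(zc),
            curves=curves,
        )

    def validate(self, conn: Connectome) -> None:
        """Abort if the pool bookkeeping disagrees with the synapse table."""
        actual = connected_counts(conn)
        if not np.array_equal(actual, self.z_connected):
            bad = np.argwhere(actual != self.z_connected)
            raise RuntimeError(
                f"element bookkeeping mismatch at (neuron, pool) {bad[:5].tolist()}: "
                f"table says {actual[tuple(bad[:5].T)]}, pools say "
                f"{self.z_connected[tuple(bad[:5].T)]}"
            )
        if (self.z_free < 0).any() or (self.z < 0).any():
            raise RuntimeError("negative element counts")


def connected_counts(conn: Connectome) -> np.ndarray:
    """(N, 3) connected-element counts implied by the synapse table."""
    n = conn.n_neurons
    zc = np.zeros((n, 3), dtype=np.int64)
    zc[:, AXONAL] = np.bincount(conn.pre, minlength=n)
    exc_src = conn.cls <= 1  # EE, EI have excitatory sources
    zc[:, POST_E] = np.bincount(conn.post[exc_src], minlength=n)
    zc[:, POST_I] = np.bincount(conn.post[~exc_src], minlength=n)
    return zc


def _pool_of_deleted(cls_code: int) -> int:
    """Dendritic pool consumed by a synapse of the given class."""
    return POST_E if cls_code <= 1 else POST_I


def structural_update(
    conn: Connectome,
    bud: BudgetArrays,
    layout: Layout,
    cfg: UpdateConfig,
    rng: np.random.Generator,
) -> dict:
    """One connectivity update; mutates ``conn`` and ``bud`` in place.

    Returns a stats dict with per-class formed/deleted counts and the total
    free elements per pool after the update.
    """
    stats = {"formed": np.zeros(4, int), "deleted": np.zeros(4, int),
             "immune_deleted": 0}

    _delete_losses(conn, bud, layout, cfg, rng, stats)

    # harvest
    surplus = np.maximum(bud.z - bud.z_connected, 0.0)
    bud.z_free = np.floor(surplus).astype(np.int64)

    _form_synapses(conn, bud, layout, cfg, rng, stats)

    # free-element decay: one floor step per growth step in the interval
    n_decay = max(int(round(cfg.interval_s / cfg.dt_growth_s)), 1)
    for _ in range(n_decay):
        new_free = np.floor(bud.z_free - cfg.tau_free * bud.z_free).astype(np.int64)
        lost = bud.z_free - new_free
        bud.z_free = new_free
        bud.z = np.maximum(bud.z - lost, 0.0)

    stats["free"] = bud.z_free.sum(axis=0)
    return stats


def _delete_losses(conn, bud, layout, cfg, rng, stats) -> None:
    is_inh = layout.is_inh
    alive = np.ones(conn.n_synapses, dtype=bool)

    # incidence lists: synapses by pre; incoming by post, split by source polarity
    order_out = np.argsort(conn.pre, kind="stable")
    out_ptr = np.concatenate([[0], np.cumsum(np.bincount(conn.pre, minlength=conn.n_neurons))])
    exc_src = conn.cls <= 1
    in_lists: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for pool, mask in ((POST_E, exc_src), (POST_I, ~exc_src)):
        idx = np.flatnonzero(mask)
        sort = idx[np.argsort(conn.post[idx], kind="stable")]
        ptr = np.concatenate(
            [[0], np.cumsum(np.bincount(conn.post[idx], minlength=conn.n_neurons))]
        )
        in_lists[pool] = (sort, ptr)

    losses = np.floor(np.maximum(bud.z_connected - bud.z, 0.0)).astype(np.int64)
    pools = np.argwhere(losses > 0)
    rng.shuffle(pools)
    for i, pool in pools:
        # recompute: earlier deletions may have already satisfied this pool
        need = int(math.floor(max(bud.z_connected[i, pool] - bud.z[i, pool], 0.0)))
        if need <= 0:
            continue
        if pool == AXONAL:
            cand = order_out[out_ptr[i] : out_ptr[i + 1]]
            weight_based = is_inh[i]
        else:
            sort, ptr = in_lists[pool]
            cand = sort[ptr[i] : ptr[i + 1]]
            weight_based = pool == POST_I
        cand = cand[alive[cand]]
        if weight_based:
            cand = cand[conn.g[cand] < cfg.g_th]  # immunity
            if len(cand) == 0:
                continue
            w = deletion_probability(conn.g[cand], cfg.g_th)
            k = min(need, len(cand))
            if w.sum() <= 0:
                chosen = rng.choice(cand, size=k, replace=False)
            else:
                chosen = rng.choice(cand, size=k, replace=False, p=w / w.sum())
        else:
            if len(cand) == 0:
                continue
            k = min(need, len(cand))
            chosen = rng.choice(cand, size=k, replace=False)
        alive[chosen] = False
        if weight_based:
            stats["immune_deleted"] += int(np.count_nonzero(conn.g[chosen] >= cfg.g_th))
        for j in chosen:
            bud.z_connected[conn.pre[j], AXONAL] -= 1
            bud.z_connected[conn.post[j], _pool_of_deleted(conn.cls[j])] -= 1
            stats["deleted"][conn.cls[j]] += 1
    dead = np.flatnonzero(~alive)
    if len(dead):
        conn.delete(dead)


def _form_synapses(conn, bud, layout, cfg, rng, stats) -> None:
    is_inh = layout.is_inh
    pos = layout.positions
    ext_x, ext_y = layout.extent
    new_pre: list[int] = []
    new_post: list[int] = []

    for inhibitory, post_pool in ((False, POST_E), (True, POST_I)):
        p_hat = cfg.p_hat_i if inhibitory else cfg.p_hat_e
        denom = (cfg.w_i if inhibitory else cfg.w_e) * cfg.mu_d_e
        src_mask = is_inh == inhibitory
        srcs = np.flatnonzero(src_mask & (bud.z_free[:, AXONAL] > 0))
        if len(srcs) == 0:
            continue
        attempts = np.repeat(srcs, bud.z_free[srcs, AXONAL])
        rng.shuffle(attempts)
        # one slot per free dendritic element, consumed by swap-remove
        hosts = np.flatnonzero(bud.z_free[:, post_pool] > 0)
        slots = np.repeat(hosts, bud.z_free[hosts, post_pool])
        m = len(slots)
        for s in attempts:
            if m == 0:
                break
            k = int(rng.integers(m))
            t = slots[k]
            if t == s:  # no autapses; this element just fails this round
                continue
            dx = abs(pos[s, 0] - pos[t, 0])
            dy = abs(pos[s, 1] - pos[t, 1])
            dx = min(dx, ext_x - dx)
            dy = min(dy, ext_y - dy)
            d = math.sqrt(dx * dx + dy * dy)
            if rng.random() < p_hat * math.exp(-((d / denom) ** 2)):
                new_pre.append(s)
                new_post.append(t)
                slots[k] = slots[m - 1]
                m -= 1
                bud.z_free[s, AXONAL] -= 1
                bud.z_free[t, post_pool] -= 1
                bud.z_connected[s, AXONAL] += 1
                bud.z_connected[t, post_pool] += 1

    if new_pre:
        pre = np.asarray(new_pre, dtype=np.int64)
        post = np.asarray(new_post, dtype=np.int64)
        cls = (2 * is_inh[pre].astype(int) + is_inh[post].astype(int)).astype(np.int8)
        means = np.array([cfg.new_conductance_mean(c) for c in range(4)])[cls]
        g = np.clip(rng.normal(means, cfg.g_sigma), a_min=0.0, a_max=None)
        conn.add(pre, post, g, cls)
        stats["formed"] += np.bincount(cls, minlength=4)
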