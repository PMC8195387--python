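"""Spatial layout, lesion-zone regions, and initial wiring of the network.

Excitatory neurons sit on a jittered rectangular lattice wrapped into a
torus; inhibitory neurons (one quarter as many) are interleaved evenly among
them on a coarser lattice. Concentric regions around the grid centre define
the lesion projection zone (LPZ): its centre (LPZ-C), inner border (LPZ-B),
the peri-LPZ ring just outside, and the remaining bulk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Layout",
    "Connectome",
    "REGION_NAMES",
    "REGION_FRACTIONS",
    "SYNAPSE_CLASSES",
    "place_neurons",
    "torus_distance",
    "classify_regions",
    "wire_initial",
]

# Region codes: radially nested, innermost first.
LPZ_C, LPZ_B, PERI_LPZ, OTHER = 0, 1, 2, 3
REGION_NAMES = ("LPZ-C", "LPZ-B", "peri-LPZ", "other")
REGION_FRACTIONS = (0.025, 0.025, 0.05, 0.90)

# Synapse class codes, keyed by (pre population, post population).
EE, EI, IE, II = 0, 1, 2, 3
SYNAPSE_CLASSES = ("EE", "EI", "IE", "II")


@dataclass(frozen=True)
class Layout:
    """Neuron positions on a torus, population identity, and grid geometry.

    Neurons are indexed 0..N-1 with all excitatory neurons first.
    ``positions`` is (N, 2) in micrometres; ``extent`` the torus periods.
    """

    positions: np.ndarray
    is_inh: np.ndarray
    extent: tuple[float, float]

    @property
    def n_neurons(self) -> int:
        return len(self.positions)

    @property
    def n_exc(self) -> int:
        return int(np.count_nonzero(~self.is_inh))

    @property
    def n_inh(self) -> int:
        return int(np.count_nonzero(self.is_inh))

    @property
    def centre(self) -> np.ndarray:
        return np.asarray(self.extent) / 2.0

    def to_frame(self, regions: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": np.arange(self.n_neurons),
                "population": np.where(self.is_inh, "I", "E"),
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
            }
        )
        if regions is not None:
            df["region"] = np.take(REGION_NAMES, regions)
        return df


def _lattice_dims(n_e: int, aspect: float) -> tuple[int, int]:
    """Even cols x even rows factorisation of ``n_e`` nearest the aspect ratio."""
    best = None
    for cols in range(2, n_e + 1, 2):
        if n_e % cols:
            continue
        rows = n_e // cols
        if rows % 2:
            continue
        score = abs(np.log((cols / rows) / aspect))
        if best is None or score < best[0]:
            best = (score, cols, rows)
    if best is None:
        raise ValueError(f"no even-by-even lattice factorisation for {n_e} neurons")
    return best[1], best[2]


def place_neurons(
    scale: float = 1.0,
    seed: int | np.random.Generator = 0,
    *,
    e_grid: tuple[int, int] = (100, 80),
    mu_d_e: float = 150.0,
    sigma_d: float = 15.0,
) -> Layout:
    """Place E and I neurons on interleaved jittered lattices.

    At full scale (``scale=1``) 8000 excitatory neurons occupy a 100x80
    lattice with 150 um mean spacing and 2000 inhibitory neurons a 50x40
    lattice with 300 um spacing, both jittered by a 15 um Gaussian and
    sharing one toroidal plane. ``scale`` shrinks each lattice dimension by
    ``sqrt(scale)``, preserving the 4:1 E:I ratio, spacing and density.
    """
    rng = np.random.default_rng(seed)
    n_e = e_grid[0] * e_grid[1] * scale
    if abs(n_e - round(n_e)) > 1e-9 or round(n_e) % 4:
        raise ValueError(
            f"scale {scale} yields a non-integral or non-multiple-of-4 E count "
            f"({n_e:.2f}); nearest feasible count is {4 * max(round(n_e / 4), 1)}"
        )
    e_cols, e_rows = _lattice_dims(int(round(n_e)), aspect=e_grid[0] / e_grid[1])
    i_cols, i_rows = e_cols // 2, e_rows // 2

    extent = (e_cols * mu_d_e, e_rows * mu_d_e)

    def lattice(cols: int, rows: int, spacing: float, offset: float) -> np.ndarray:
        gx, gy = np.meshgrid(np.arange(cols), np.arange(rows), indexing="ij")
        pos = np.column_stack([gx.ravel(), gy.ravel()]).astype(float) * spacing + offset
        pos += rng.normal(0.0, sigma_d, size=pos.shape)
        return np.mod(pos, extent)

    # I lattice offset by half its spacing so I neurons sit between E neurons.
    pos_e = lattice(e_cols, e_rows, mu_d_e, 0.0)
    pos_i = lattice(i_cols, i_rows, 2.0 * mu_d_e, 0.5 * mu_d_e)

    positions = np.vstack([pos_e, pos_i])
    is_inh = np.zeros(len(positions), dtype=bool)
    is_inh[len(pos_e):] = True
    return Layout(positions=positions, is_inh=is_inh, extent=extent)


def torus_distance(a: np.ndarray, b: np.ndarray, extent: tuple[float, float]) -> np.ndarray:
    """Minimum-image Euclidean distance on the torus. Broadcasts over rows."""
    delta = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    ext = np.asarray(extent, dtype=float)
    delta = np.minimum(delta, ext - delta)
    return np.sqrt((delta**2).sum(axis=-1))


def classify_regions(layout: Layout) -> np.ndarray:
    """Assign each neuron a region by distance rank from the grid centre.

    Within each population independently, the nearest 2.5% of neurons to the
    torus centre form LPZ-C, the next 2.5% LPZ-B, the next 5% the peri-LPZ,
    and the rest "other". Ranking per population keeps the E:I ratio uniform
    across regions and hits the stated fractions exactly (to rounding).
    """
    regions = np.full(layout.n_neurons, OTHER, dtype=np.int8)
    dist = torus_distance(layout.positions, layout.centre, layout.extent)
    for pop_mask in (~layout.is_inh, layout.is_inh):
        idx = np.flatnonzero(pop_mask)
        order = idx[np.argsort(dist[idx], kind="stable")]
        n = len(idx)
        n_c = round(REGION_FRACTIONS[0] * n)
        n_b = round(REGION_FRACTIONS[1] * n)
        n_p = round(REGION_FRACTIONS[2] * n)
        regions[order[:n_c]] = LPZ_C
        regions[order[n_c : n_c + n_b]] = LPZ_B
        regions[order[n_c + n_b : n_c + n_b + n_p]] = PERI_LPZ
    return regions


@dataclass
class Connectome:
    """The mutable synapse table: parallel arrays of edges plus conductances.

    ``cls`` encodes the synapse class from the populations of the endpoints
    (EE, EI, IE, II). Multiple parallel synapses between an ordered pair are
    allowed; autapses are not.
    """

    pre: np.ndarray
    post: np.ndarray
    g: np.ndarray
    cls: np.ndarray
    n_neurons: int = 0

    @property
    def n_synapses(self) -> int:
        return len(self.pre)

    def sparsity(self) -> float:
        n = self.n_neurons
        return self.n_synapses / (n * (n - 1))

    def out_degree(self) -> np.ndarray:
        return np.bincount(self.pre, minlength=self.n_neurons)

    def in_degree(self, classes: tuple[int, ...] | None = None) -> np.ndarray:
        if classes is None:
            return np.bincount(self.post, minlength=self.n_neurons)
        mask = np.isin(self.cls, classes)
        return np.bincount(self.post[mask], minlength=self.n_neurons)

    def copy(self) -> "Connectome":
        return Connectome(
            self.pre.copy(), self.post.copy(), self.g.copy(), self.cls.copy(), self.n_neurons
        )

    def delete(self, indices: np.ndarray) -> None:
        keep = np.ones(self.n_synapses, dtype=bool)
        keep[indices] = False
        self.pre, self.post = self.pre[keep], self.post[keep]
        self.g, self.cls = self.g[keep], self.cls[keep]

    def add(self, pre: np.ndarray, post: np.ndarray, g: np.ndarray, cls: np.ndarray) -> None:
        self.pre = np.concatenate([self.pre, np.asarray(pre, dtype=self.pre.dtype)])
        self.post = np.concatenate([self.post, np.asarray(post, dtype=self.post.dtype)])
        self.g = np.concatenate([self.g, np.asarray(g, dtype=float)])
        self.cls = np.concatenate([self.cls, np.asarray(cls, dtype=self.cls.dtype)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pre_id": self.pre,
                "post_id": self.post,
                "class": np.take(SYNAPSE_CLASSES, self.cls),
                "g_nS": self.g,
            }
        )

    def to_csv(self, path, t_s: float | None = None) -> None:
        df = self.to_frame()
        if t_s is not None:
            df["t_s"] = t_s
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_neurons: int) -> "Connectome":
        df = pd.read_csv(path)
        code = {name: i for i, name in enumerate(SYNAPSE_CLASSES)}
        return cls(
            pre=df["pre_id"].to_numpy(np.int64),
            post=df["post_id"].to_numpy(np.int64),
            g=df["g_nS"].to_numpy(float),
            cls=df["class"].map(code).to_numpy(np.int8),
            n_neurons=n_neurons,
        )


def synapse_class(is_inh_pre: np.ndarray, is_inh_post: np.ndarray) -> np.ndarray:
    """Class code from endpoint populations (EE, EI, IE, II)."""
    return (2 * np.asarray(is_inh_pre, int) + np.asarray(is_inh_post, int)).astype(np.int8)


def wire_initial(
    layout: Layout,
    p: float = 0.02,
    *,
    g_unit: float = 0.5,
    g_sigma: float = 0.1,
    w_e: float = 8.0,
    w_i: float = 24.0,
    mu_d_e: float = 150.0,
    seed: int | np.random.Generator = 0,
) -> Connectome:
    """Wire the initial sparse connectome with distance-dependent targets.

    Every neuron projects to exactly ``n_out = round(p * (N - 1))`` targets,
    sampled without replacement and without autapses, weighted by the same
    Gaussian spatial kernel used for synapse formation during rewiring:
    exp(-(d / (w * mu_d_e))**2) with the wider multiplier ``w_i`` for
    inhibitory sources. Static conductances are drawn from N(mean, g_sigma)
    clipped positive with mean ``g_unit`` for EE/EI and ``10 * g_unit`` for
    II; plastic IE synapses start at zero conductance.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("connection probability p must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = layout.n_neurons
    n_out = round(p * (n - 1))
    if n_out < 1 or n_out > n - 1:
        raise ValueError(f"out-degree {n_out} infeasible for {n} neurons")

    pre = np.empty(n * n_out, dtype=np.int64)
    post = np.empty(n * n_out, dtype=np.int64)
    for i in range(n):
        d = torus_distance(layout.positions, layout.positions[i], layout.extent)
        w = w_i if layout.is_inh[i] else w_e
        logw = -((d / (w * mu_d_e)) ** 2)
        logw[i] = -np.inf  # no autapses
        # Gumbel top-k gives a weighted sample without replacement.
        keys = logw + rng.gumbel(size=n)
        targets = np.argpartition(-keys, n_out)[:n_out]
        pre[i * n_out : (i + 1) * n_out] = i
        post[i * n_out : (i + 1) * n_out] = targets

    cls = synapse_class(layout.is_inh[pre], layout.is_inh[post])
    means = np.array([g_unit, g_unit, 0.0, 10.0 * g_unit])[cls]
    g = np.clip(rng.normal(means, g_sigma), a_min=1e-6, a_max=None)
    g[cls == IE] = 0.0
    return Connectome(pre=pre, post=post, g=g, cls=cls, n_neurons=n)
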