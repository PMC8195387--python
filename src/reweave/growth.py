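"""Activity-dependent neurite growth rules and synaptic-element bookkeeping.

The model abstracts axons and dendrites into countable *synaptic elements*:
pre-synaptic (axonal) contact points and post-synaptic (dendritic) ones, of
excitatory or inhibitory polarity. Each neuron maintains a continuous element
count ``z`` per element class, driven by a Gaussian function of the neuron's
calcium trace — a slow exponential average of its spiking used as an activity
proxy. A synapse exists when a free pre-element is bound to a free
post-element of matching polarity; the integer book-keeping of connected,
free and lost elements lives here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GrowthCurve",
    "CalciumTrace",
    "ElementPool",
    "growth_rate",
    "curve_extrema",
    "update_calcium",
    "integrate_elements",
    "harvest_free_elements",
    "decay_free_elements",
    "count_losses",
]


@dataclass(frozen=True)
class GrowthCurve:
    """Gaussian growth rule for one synaptic-element class.

    The turnover rate of elements as a function of the calcium trace ``ca`` is

        dz/dt = nu * (2 * exp(-((ca - xi) / zeta)**2) - omega)

    with midpoint ``xi = (eta + epsilon) / 2`` and width
    ``zeta = (epsilon - eta) / (2 * sqrt(-ln(omega / 2)))``, so that the rate
    crosses zero exactly at ``eta`` and ``epsilon``. Elements sprout for
    ``eta < ca < epsilon`` and retract outside that window. ``omega`` shifts
    the curve vertically: the asymptotic retraction rate is ``-nu * omega``
    and the peak sprouting rate ``nu * (2 - omega)``, attained at ``xi``.

    Parameters
    ----------
    nu : float
        Scaling factor, elements per unit time (>= 0).
    eta, epsilon : float
        Lower and upper zero-crossings, in calcium units (eta < epsilon).
    omega : float
        Vertical shift, dimensionless, in (0, 2) so the width is real.
    """

    nu: float
    eta: float
    epsilon: float
    omega: float = 1.0
    xi: float = field(init=False)
    zeta: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.eta < self.epsilon:
            raise ValueError(f"require eta < epsilon, got {self.eta} >= {self.epsilon}")
        if self.nu < 0:
            raise ValueError(f"nu must be >= 0, got {self.nu}")
        if not 0.0 < self.omega < 2.0:
            raise ValueError(f"omega must lie in (0, 2), got {self.omega}")
        object.__setattr__(self, "xi", 0.5 * (self.eta + self.epsilon))
        object.__setattr__(
            self,
            "zeta",
            (self.epsilon - self.eta) / (2.0 * math.sqrt(-math.log(self.omega / 2.0))),
        )

    @classmethod
    def constant(cls, rate: float) -> "GrowthCurve":
        """Activity-independent sprouting at ``rate`` elements per unit time.

        Realised as a Gaussian window vastly wider than any attainable
        calcium value, so dz/dt is ``rate`` to machine precision everywhere
        on the physical domain ca >= 0.
        """
        if rate < 0:
            raise ValueError("constant sprouting rate must be >= 0")
        return cls(nu=rate, eta=-1e15, epsilon=1e15, omega=1.0)

    @classmethod
    def silent(cls) -> "GrowthCurve":
        """No turnover at any activity (nu = 0)."""
        return cls(nu=0.0, eta=0.0, epsilon=1.0, omega=1.0)

    def __call__(self, ca):
        return growth_rate(self, ca)


def growth_rate(curve: GrowthCurve, ca):
    """Element turnover rate dz/dt at calcium value(s) ``ca``.

    Positive iff ``eta < ca < epsilon``; zero at the crossings; approaches
    ``-nu * omega`` for large ``ca``. Accepts scalars or arrays.
    """
    ca = np.asarray(ca, dtype=float)
    rate = curve.nu * (2.0 * np.exp(-(((ca - curve.xi) / curve.zeta) ** 2)) - curve.omega)
    return rate if rate.ndim else float(rate)


def curve_extrema(curve: GrowthCurve) -> tuple[float, float, float]:
    """(asymptotic infimum, maximum, calcium at the maximum).

    The infimum ``-nu * omega`` is approached as ca -> inf; the maximum
    ``nu * (2 - omega)`` is attained at the curve midpoint.
    """
    return (-curve.nu * curve.omega, curve.nu * (2.0 - curve.omega), curve.xi)


@dataclass(frozen=True)
class CalciumTrace:
    """Per-neuron calcium concentration: a leaky integrator of spiking.

    Decays exponentially with time constant ``tau_ca`` (seconds) and jumps by
    ``beta`` at each spike, so its mean under Poisson firing at rate r is
    ``beta * r * tau_ca``.
    """

    ca: float = 0.0
    beta: float = 0.1
    tau_ca: float = 50.0

    def __post_init__(self) -> None:
        if self.ca < 0:
            raise ValueError("calcium concentration cannot be negative")
        if self.tau_ca <= 0:
            raise ValueError("tau_ca must be positive")


def update_calcium(trace: CalciumTrace, n_spikes: int, dt: float) -> CalciumTrace:
    """Advance a calcium trace by ``dt`` seconds with ``n_spikes`` spikes.

    Decay is applied over the interval, then each spike contributes an
    instantaneous increment ``beta``.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if n_spikes < 0:
        raise ValueError("spike count must be >= 0")
    ca = trace.ca * math.exp(-dt / trace.tau_ca) + trace.beta * n_spikes
    return replace(trace, ca=ca)


@dataclass
class ElementPool:
    """Element counts for one class at one neuron.

    ``z`` is the continuous count produced by the growth rule; ``z_connected``
    the integer number currently bound in synapses; ``z_free`` the integer
    number available for new synapses (harvested as floor(z - z_connected)).
    Free elements decay with per-step rate ``tau_free``.
    """

    z: float = 0.0
    z_connected: int = 0
    z_free: int = 0
    tau_free: float = 0.01

    def __post_init__(self) -> None:
        if self.z < 0 or self.z_connected < 0 or self.z_free < 0:
            raise ValueError("element counts cannot be negative")


def integrate_elements(
    pool: ElementPool, curve: GrowthCurve, ca: float, n_steps: int, dt: float = 1.0
) -> ElementPool:
    """Grow/retract the continuous count over ``n_steps`` steps of ``dt``.

    The total is clamped at zero from below: element counts are physical.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    z = max(pool.z + growth_rate(curve, ca) * n_steps * dt, 0.0)
    return replace(pool, z=z)


def harvest_free_elements(pool: ElementPool) -> int:
    """Integer count of unbound elements available for synapse formation."""
    surplus = pool.z - pool.z_connected
    return int(math.floor(surplus)) if surplus > 0 else 0


def decay_free_elements(pool: ElementPool) -> ElementPool:
    """Apply one decay step to the free elements.

    z_free <- floor(z_free - tau_free * z_free); the continuous total ``z`` is
    reduced by the same amount so decayed elements are not resurrected at the
    next harvest.
    """
    new_free = int(math.floor(pool.z_free - pool.tau_free * pool.z_free))
    lost = pool.z_free - new_free
    return replace(pool, z_free=new_free, z=max(pool.z - lost, 0.0))


def count_losses(pool: ElementPool) -> int:
    """Number of synapses the pool must shed because z fell below z_connected."""
    deficit = pool.z_connected - pool.z
    return int(math.floor(deficit)) if deficit > 0 else 0
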