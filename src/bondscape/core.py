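"""Domain types and physical constants for single-molecule force spectroscopy.

The package works in the unit system native to AFM force spectroscopy:
forces in pN, distances in nm, times in s (velocities in µm/s and contact
times in ms, following instrument conventions). Energies are then naturally
in pN·nm, and the Boltzmann constant is 1.380649e-2 pN·nm/K, so that
k_B·T ≈ 4.11 pN·nm at room temperature.

Adhesion forces are stored as positive magnitudes: a rupture event of
50 pN means the cantilever pulled with 50 pN when the bond broke. With
this convention the bond lifetime under load is a *decaying* exponential,
t(F) = t0·exp(−x_β F / k_B T), where t0 is the (longest) lifetime at
thermal equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Boltzmann constant in pN·nm/K (exact, from the SI definition of k_B).
BOLTZMANN_PN_NM_PER_K = 1.380649e-2

#: Room temperature in K; all default analyses assume this.
ROOM_TEMPERATURE_K = 298.15


class BondscapeError(Exception):
    """Base class for package errors."""


class InvalidEnvironmentError(BondscapeError):
    """Raised for unphysical environment parameters (e.g. T ≤ 0)."""


class DomainError(BondscapeError):
    """Raised when an argument is outside the physical domain of an operation."""


class InsufficientDataError(BondscapeError):
    """Raised when a computation has too few samples to be meaningful."""


class FitError(BondscapeError):
    """Raised when a model fit cannot be performed or does not converge."""


@dataclass(frozen=True)
class Environment:
    """Thermal environment of the experiment.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K. Default is room temperature (298.15 K).
    boltzmann : float
        Boltzmann constant in pN·nm/K. Exposed so that the unit system is
        explicit; there is no reason to change it.
    """

    temperature: float = ROOM_TEMPERATURE_K
    boltzmann: float = BOLTZMANN_PN_NM_PER_K

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise InvalidEnvironmentError(
                f"temperature must be > 0 K, got {self.temperature}"
            )
        if not (self.boltzmann > 0):
            raise InvalidEnvironmentError("boltzmann constant must be positive")


def thermal_energy(env: Environment) -> float:
    """Thermal energy k_B·T in pN·nm.

    >>> round(thermal_energy(Environment()), 4)
    4.1164
    """
    return env.boltzmann * env.temperature


@dataclass
class ForceCurve:
    """One force–distance record (approach or retract segment).

    ``separation`` is the tip–sample separation in nm, already corrected
    for cantilever deflection, with 0 at the contact point. ``force`` is
    the adhesion force magnitude in pN, one sample per separation value.
    Retract segments are ordered by increasing separation.
    """

    separation: np.ndarray
    force: np.ndarray
    segment: str = "retract"
    spring_constant: float = 70.0  # pN/nm
    pulling_velocity: float = 3.1  # µm/s
    contact_time: float = 2.0  # ms
    sample_label: str = "wt"
    curve_id: str = "curve-0"

    def __post_init__(self) -> None:
        self.separation = np.asarray(self.separation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.separation.ndim != 1 or self.force.ndim != 1:
            raise DomainError("separation and force must be 1-D arrays")
        if self.separation.size != self.force.size:
            raise DomainError(
                f"separation ({self.separation.size}) and force "
                f"({self.force.size}) must have equal length"
            )
        if self.separation.size < 16:
            raise DomainError("a force curve needs at least 16 samples")
        if self.segment not in ("approach", "retract"):
            raise DomainError(f"segment must be approach|retract, got {self.segment!r}")
        if not (self.spring_constant > 0):
            raise DomainError("spring_constant must be > 0")
        if not (self.pulling_velocity > 0):
            raise DomainError("pulling_velocity must be > 0")
        if self.contact_time < 0:
            raise DomainError("contact_time must be >= 0")
        if self.segment == "retract" and np.any(np.diff(self.separation) <= 0):
            raise DomainError("retract separation must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return int(self.separation.size)


@dataclass
class ClampTrace:
    """One height-clamp force–time record: uniform time grid (s), force (pN)."""

    time: np.ndarray
    force: np.ndarray
    clamp_height: float = 7.5  # nm above the membrane surface
    trace_id: str = "trace-0"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.size != self.force.size:
            raise DomainError("time and force must have equal length")
        if self.time.size < 16:
            raise DomainError("a clamp trace needs at least 16 samples")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise DomainError("time must be strictly increasing")
        mean_step = steps.mean()
        if np.max(np.abs(steps - mean_step)) > 0.01 * mean_step:
            raise DomainError("time sampling must be uniform within 1%")

    @property
    def dt(self) -> float:
        return float(np.diff(self.time).mean())


@dataclass
class RuptureEvent:
    """A single unbinding event detected on a retract force curve.

    ``loading_rate`` is NaN when it could not be determined (too few
    samples on the force rise); such events are kept for force
    distributions but excluded from dynamic force spectroscopy reduction.
    """

    rupture_distance: float  # nm from the contact point
    rupture_force: float  # pN, positive magnitude
    loading_rate: float = math.nan  # pN/s
    specific: bool = False
    curve_id: str = ""

    def __post_init__(self) -> None:
        if self.rupture_force < 0:
            raise DomainError("rupture_force must be >= 0")
        if not math.isnan(self.loading_rate) and self.loading_rate <= 0:
            raise DomainError("loading_rate must be > 0 when defined")

    @property
    def has_loading_rate(self) -> bool:
        return not math.isnan(self.loading_rate)


@dataclass
class ClampEvent:
    """A single binding event from a height-clamp trace: lifetime Δt and force step ΔF."""

    lifetime: float  # s
    force_step: float  # pN
    trace_id: str = ""

    def __post_init__(self) -> None:
        if not (self.lifetime > 0):
            raise DomainError("lifetime must be > 0")
        if not (self.force_step > 0):
            raise DomainError("force_step must be > 0")


@dataclass
class BellParams:
    """Bell-model fit result: equilibrium lifetime t0 and barrier distance x_β.

    ``t0_ci`` / ``x_beta_ci`` are 95% confidence half-widths from the fit
    covariance (reported as ±CI).
    """

    t0: float  # s
    x_beta: float  # nm
    t0_ci: float = math.nan
    x_beta_ci: float = math.nan

    def __post_init__(self) -> None:
        if not (self.t0 > 0):
            raise DomainError("t0 must be > 0")
        if not (self.x_beta > 0):
            raise DomainError("x_beta must be > 0")

    @property
    def k0(self) -> float:
        """Zero-force off-rate, the reciprocal of the equilibrium lifetime."""
        return 1.0 / self.t0


@dataclass
class BellEvansFit:
    """Bell–Evans fit result with the Arrhenius barrier height.

    ``delta_g`` is in units of k_B·T and always satisfies
    delta_g = −ln(tau_d · k0); constructing a fit with an inconsistent
    value is an error. ``delta_g_err`` is the first-order propagated error
    k0_ci / k0.
    """

    k0: float  # 1/s
    x_beta: float  # nm
    delta_g: float  # k_B T
    k0_ci: float = math.nan
    x_beta_ci: float = math.nan
    delta_g_err: float = math.nan
    tau_d: float = 1e-5  # s, diffusive relaxation time

    def __post_init__(self) -> None:
        if not (self.k0 > 0):
            raise DomainError("k0 must be > 0")
        if not (self.x_beta > 0):
            raise DomainError("x_beta must be > 0")
        if not (self.tau_d > 0):
            raise DomainError("tau_d must be > 0")
        expected = -math.log(self.tau_d * self.k0)
        if not math.isclose(self.delta_g, expected, rel_tol=0, abs_tol=1e-9):
            raise DomainError(
                f"delta_g={self.delta_g} inconsistent with -ln(tau_d*k0)={expected}"
            )

    @property
    def lifetime(self) -> float:
        return 1.0 / self.k0


@dataclass
class DfsPoint:
    """Per-velocity dynamic force spectroscopy reduction.

    Most probable rupture force and most probable loading rate (both kernel
    density estimation modes) for one pulling velocity, with the number of
    events behind them.
    """

    velocity: float  # µm/s
    mp_force: float  # pN
    mp_loading_rate: float  # pN/s
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("n must be >= 1")
        if not (self.mp_loading_rate > 0):
            raise DomainError("mp_loading_rate must be > 0")
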