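"""Monte-Carlo generation of bond-rupture events and synthetic AFM recordings.

The generator emulates the two experimental protocols the analysis is built
for, with known ground truth so that every downstream stage (event
detection, kinetic fitting) can be validated by parameter recovery:

* **Height clamp**: the bond is held under a constant force F and its
  lifetime is exponentially distributed with mean t(F) = t0·exp(−x_β F/k_BT)
  (a slip bond obeying Bell kinetics). Traces are square force pulses on a
  noisy zero baseline.

* **Force ramp** (dynamic force spectroscopy): the force grows at a
  constant loading rate LR until the bond breaks. With a Bell off-rate
  k(F) = k0·exp(x_β F/k_BT), the rupture-force survival law is

      S(F) = exp[ (k0 k_BT)/(x_β LR) · (1 − exp(x_β F/k_BT)) ],

  sampled exactly by inverse-CDF. Rupture events are rendered into
  force–distance curves as worm-like-chain (WLC) force rises through a
  PEG linker (≈9 nm stretched contour) plus an unfolded-polypeptide
  contribution (≈6 nm), detaching abruptly at the rupture point, on a
  Gaussian baseline of ≈3 pN sd — so that the five-sigma detection
  threshold sits at ≈15 pN, as in the experiments being emulated.

Loading rates scatter log-normally (20% cv by default) around the nominal
stiffness × velocity value, reflecting the empirical per-velocity loading
rate distributions of real pulling experiments. The effective stiffness is
the series combination of the cantilever (70 pN/nm nominal) and the WLC
linker stiffness near rupture.

All generators draw from an explicit ``numpy.random.Generator`` and are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import (
    ClampTrace,
    DomainError,
    Environment,
    ForceCurve,
    thermal_energy,
)


@dataclass(frozen=True)
class BondModel:
    """A slip bond with Bell kinetics: zero-force off-rate k0 and barrier distance x_β."""

    k0: float  # 1/s
    x_beta: float  # nm
    env: Environment = Environment()

    def __post_init__(self) -> None:
        if not (self.k0 > 0):
            raise DomainError("k0 must be > 0")
        if self.x_beta < 0:
            raise DomainError("x_beta must be >= 0")

    @property
    def t0(self) -> float:
        return 1.0 / self.k0

    def mean_lifetime(self, force) -> np.ndarray | float:
        """Mean bond lifetime t0·exp(−x_β F/k_BT) under constant force (pN)."""
        kbt = thermal_energy(self.env)
        return self.t0 * np.exp(-self.x_beta * np.asarray(force, dtype=float) / kbt)


def sample_bond_lifetime(force, bond: BondModel, rng: np.random.Generator, size=None):
    """Draw exponentially distributed lifetimes under a constant force (pN)."""
    force = np.asarray(force, dtype=float)
    if np.any(force < 0):
        raise DomainError("force must be >= 0 (positive adhesion magnitude)")
    return rng.exponential(bond.mean_lifetime(force), size=size)


def rupture_force_survival(force, loading_rate: float, bond: BondModel):
    """Analytic survival probability S(F) of a Bell bond under a constant force ramp."""
    if not (loading_rate > 0):
        raise DomainError("loading_rate must be > 0")
    kbt = thermal_energy(bond.env)
    f = np.asarray(force, dtype=float)
    if bond.x_beta == 0:
        return np.exp(-bond.k0 * f / loading_rate)
    a = bond.k0 * kbt / (bond.x_beta * loading_rate)
    return np.exp(a * (1.0 - np.exp(bond.x_beta * f / kbt)))


def sample_rupture_force(loading_rate: float, bond: BondModel,
                         rng: np.random.Generator, size=None):
    """Draw rupture forces from the force-ramp survival law by inverse CDF.

    F = (k_BT/x_β)·ln(1 − (x_β·LR)/(k0·k_BT)·ln U), U ~ Uniform(0, 1).
    """
    if not (loading_rate > 0):
        raise DomainError("loading_rate must be > 0")
    u = rng.uniform(size=size)
    log_u = np.log(u)
    kbt = thermal_energy(bond.env)
    if bond.x_beta == 0:
        return -loading_rate * log_u / bond.k0
    return (kbt / bond.x_beta) * np.log1p(
        -(bond.x_beta * loading_rate) / (bond.k0 * kbt) * log_u
    )


class ModeForce(float):
    """Most probable rupture force; ``below_threshold`` flags a non-existent mode."""

    below_threshold: bool = False

    def __new__(cls, value: float, below_threshold: bool = False):
        obj = super().__new__(cls, value)
        obj.below_threshold = below_threshold
        return obj


def most_probable_rupture_force(loading_rate: float, bond: BondModel) -> ModeForce:
    """Closed-form mode of the rupture-force distribution (Bell–Evans).

    F* = (k_BT/x_β)·ln(LR·x_β/(k0·k_BT)); when the argument of the log is
    ≤ 1 the distribution has its maximum at zero force and the result is
    0 with ``below_threshold`` set.
    """
    if not (loading_rate > 0):
        raise DomainError("loading_rate must be > 0")
    if bond.x_beta == 0:
        return ModeForce(0.0, below_threshold=True)
    kbt = thermal_energy(bond.env)
    arg = loading_rate * bond.x_beta / (bond.k0 * kbt)
    if arg <= 1:
        return ModeForce(0.0, below_threshold=True)
    return ModeForce((kbt / bond.x_beta) * math.log(arg))


@dataclass(frozen=True)
class CurveSynthesisSpec:
    """Parameters shaping synthetic retract force–distance curves.

    ``linker_contour`` is the stretched PEG linker length (≈9 nm for 27
    monomers); ``extra_contour`` adds the unfolded polypeptide stretch so
    the total tether contour is ≈15 nm and specific events fall in the
    5–25 nm separation window. ``noise_sd`` defaults to 3 pN so that the
    5×sd specific-event threshold is ≈15 pN.
    """

    noise_sd: float = 3.0  # pN
    linker_contour: float = 9.0  # nm
    linker_persistence: float = 0.38  # nm
    extra_contour: float = 6.0  # nm
    nonspecific_prob: float = 0.1
    pulling_velocity: float = 3.1  # µm/s
    spring_constant: float = 70.0  # pN/nm
    samples_per_curve: int = 512
    max_separation: float = 40.0  # nm (instrument ramp size)
    contact_time: float = 52.0  # ms, stamped on generated curves
    sample_label: str = "wt"
    env: Environment = Environment()
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if not (self.linker_contour > 0 and self.extra_contour >= 0):
            raise DomainError("contour lengths must be positive")
        if not (0 <= self.nonspecific_prob <= 1):
            raise DomainError("nonspecific_prob must be in [0, 1]")
        if self.samples_per_curve < 16:
            raise DomainError("samples_per_curve must be >= 16")

    @property
    def total_contour(self) -> float:
        return self.linker_contour + self.extra_contour


def linker_extension_force(extension: float, spec: CurveSynthesisSpec):
    """Worm-like-chain interpolation force (pN) at a given tether extension (nm).

    F(x) = (k_BT/Lp)·[1/(4(1−x/Lc)²) − 1/4 + x/Lc] with Lc the total
    tether contour; monotone increasing and divergent as x → Lc.
    """
    x = np.asarray(extension, dtype=float)
    lc = spec.total_contour
    if np.any(x < 0) or np.any(x >= lc):
        raise DomainError(f"extension must be in [0, {lc}) nm")
    t = x / lc
    kbt = thermal_energy(spec.env)
    out = (kbt / spec.linker_persistence) * (0.25 / (1.0 - t) ** 2 - 0.25 + t)
    return float(out) if np.isscalar(extension) else out


def extension_at_force(force: float, spec: CurveSynthesisSpec) -> float:
    """Inverse of :func:`linker_extension_force` (extension in nm at a given force)."""
    if force < 0:
        raise DomainError("force must be >= 0")
    if force == 0:
        return 0.0
    lc = spec.total_contour
    kbt = thermal_energy(spec.env)

    def g(t):
        return (kbt / spec.linker_persistence) * (0.25 / (1.0 - t) ** 2 - 0.25 + t) - force

    return lc * brentq(g, 0.0, 1.0 - 1e-9, xtol=1e-12)


def wlc_stiffness(extension: float, spec: CurveSynthesisSpec) -> float:
    """dF/dx of the WLC interpolation at a given extension (pN/nm)."""
    lc = spec.total_contour
    t = extension / lc
    kbt = thermal_energy(spec.env)
    return (kbt / (spec.linker_persistence * lc)) * (0.5 / (1.0 - t) ** 3 + 1.0)


def effective_spring_constant(spec: CurveSynthesisSpec, at_fraction: float = 0.72) -> float:
    """Series stiffness of cantilever and WLC tether near rupture (pN/nm).

    ``at_fraction`` is the extension fraction x/Lc at which the tether
    stiffness is evaluated (≈0.7–0.75 at typical rupture forces).
    """
    k_tether = wlc_stiffness(at_fraction * spec.total_contour, spec)
    return spec.spring_constant * k_tether / (spec.spring_constant + k_tether)


def synthesize_retract_curve(
    events: list[tuple[float, float]],
    spec: CurveSynthesisSpec,
    rng: np.random.Generator,
    curve_id: str = "synthetic-0",
) -> tuple[ForceCurve, list[dict]]:
    """Render rupture events into a noisy retract force–distance curve.

    ``events`` is a list of (rupture_distance nm, rupture_force pN). Each
    event appears as a WLC force rise reaching its rupture force at the
    rupture separation and detaching abruptly there. With probability
    ``nonspecific_prob`` a short-range (<5 nm) non-specific adhesion is
    added. Returns the curve and its ground-truth annotation (one dict per
    rendered rupture, plus any non-specific adhesion).
    """
    sep = np.linspace(0.0, spec.max_separation, spec.samples_per_curve)
    force = np.zeros_like(sep)
    kbt = thermal_energy(spec.env)

    distances = sorted(d for d, _ in events)
    if any(b - a < 1.0 for a, b in zip(distances, distances[1:])):
        raise DomainError("rupture separations closer than 1 nm overlap")

    truth: list[dict] = []
    for dist, f_rup in sorted(events):
        if not (0 < dist < spec.max_separation):
            raise DomainError(f"event distance {dist} nm outside sampled range")
        if f_rup <= 0:
            raise DomainError("event force must be > 0")

        # contour of this event's tether so that the WLC rise hits f_rup at dist
        def g(t, _f=f_rup):
            return (kbt / spec.linker_persistence) * (0.25 / (1 - t) ** 2 - 0.25 + t) - _f

        t_rup = brentq(g, 1e-12, 1.0 - 1e-9, xtol=1e-12)
        lc_event = dist / t_rup
        rising = sep <= dist
        t = sep[rising] / lc_event
        force[rising] += (kbt / spec.linker_persistence) * (
            0.25 / (1.0 - t) ** 2 - 0.25 + t
        )
        truth.append(
            {"curve_id": curve_id, "kind": "specific", "distance": float(dist),
             "force": float(f_rup)}
        )

    if rng.uniform() < spec.nonspecific_prob:
        amp = rng.uniform(20.0, 80.0)
        force += amp * np.exp(-sep / 1.2)
        truth.append(
            {"curve_id": curve_id, "kind": "nonspecific", "distance": 0.0,
             "force": float(amp)}
        )

    if spec.noise_sd > 0:
        force += rng.normal(0.0, spec.noise_sd, size=sep.size)

    curve = ForceCurve(
        separation=sep,
        force=force,
        segment="retract",
        spring_constant=spec.spring_constant,
        pulling_velocity=spec.pulling_velocity,
        contact_time=spec.contact_time,
        sample_label=spec.sample_label,
        curve_id=curve_id,
    )
    return curve, truth


def synthesize_clamp_trace(
    events: list[tuple[float, float, float]],
    duration: float = 1.5,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
    dt: float = 5e-4,
    clamp_height: float = 7.5,
    trace_id: str = "synthetic-trace-0",
) -> tuple[ClampTrace, list[dict]]:
    """Render binding events as square force pulses on a noisy zero baseline.

    ``events`` is a list of (start s, lifetime s, force_step pN),
    non-overlapping. Pulses extending past the trace end are clipped (and
    should be rejected by extraction, which requires events to start and
    end at the baseline).
    """
    if rng is None:
        rng = np.random.default_rng()
    n = int(round(duration / dt))
    time = np.arange(n) * dt
    force = np.zeros(n)
    ordered = sorted(events)
    for (s0, l0, _), (s1, _, _) in zip(ordered, ordered[1:]):
        if s0 + l0 > s1:
            raise DomainError("clamp events overlap")
    truth = []
    for start, lifetime, step in ordered:
        if start < 0 or lifetime <= 0 or step <= 0:
            raise DomainError("clamp event needs start >= 0, lifetime > 0, step > 0")
        i0 = int(round(start / dt))
        i1 = min(int(round((start + lifetime) / dt)), n)
        if i0 >= n:
            raise DomainError(f"event at {start} s starts beyond the trace")
        force[i0:i1] += step
        truth.append(
            {"trace_id": trace_id, "start": float(start), "lifetime": float(lifetime),
             "force_step": float(step), "truncated": i1 >= n}
        )
    if noise_sd > 0:
        force += rng.normal(0.0, noise_sd, size=n)
    trace = ClampTrace(time=time, force=force, clamp_height=clamp_height,
                       trace_id=trace_id)
    return trace, truth


@dataclass(frozen=True)
class ExperimentConfig:
    """Conditions of a simulated pulling experiment.

    Defaults mirror the emulated protocols: five pulling velocities from
    1 to 25 µm/s, contact times from 2 to 502 ms, clamp forces spanning
    20–120 pN, and ~92 events per velocity (≈460 events in a five-velocity
    dataset).
    """

    bond: BondModel
    velocities: tuple[float, ...] = (1.0, 3.1, 6.3, 12.5, 25.0)
    events_per_velocity: int = 92
    contact_times: tuple[float, ...] = (2, 3, 4, 12, 22, 52, 502)
    clamp_force_range: tuple[float, float] = (20.0, 120.0)
    loading_rate_cv: float = 0.2
    curve_spec: CurveSynthesisSpec = field(default_factory=CurveSynthesisSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.velocities):
            raise DomainError("all velocities must be > 0")
        if self.events_per_velocity < 1:
            raise DomainError("events_per_velocity must be >= 1")
        if not (0 <= self.loading_rate_cv < 1):
            raise DomainError("loading_rate_cv must be in [0, 1)")
        lo, hi = self.clamp_force_range
        if not (0 <= lo < hi):
            raise DomainError("clamp_force_range must be an increasing pair")


def generate_dfs_events(
    config: ExperimentConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Sample ground-truth rupture events for every velocity (no curve rendering).

    Per event the loading rate is the effective stiffness × velocity with
    median-preserving log-normal scatter (cv ``loading_rate_cv``); the
    rupture force is drawn from the Bell survival law at that loading rate.
    Returns a DataFrame with columns velocity, loading_rate, rupture_force.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    keff = effective_spring_constant(config.curve_spec)
    sigma = math.sqrt(math.log(1.0 + config.loading_rate_cv**2))
    rows = []
    for v in config.velocities:
        nominal = keff * v * 1000.0  # pN/nm × nm/s(=µm/s·1000) → pN/s
        lrs = nominal * rng.lognormal(mean=0.0, sigma=sigma,
                                      size=config.events_per_velocity)
        for lr in lrs:
            f = float(sample_rupture_force(float(lr), config.bond, rng))
            rows.append({"velocity": v, "loading_rate": float(lr), "rupture_force": f})
    return pd.DataFrame(rows)


def generate_dfs_dataset(
    config: ExperimentConfig,
) -> tuple[list[ForceCurve], pd.DataFrame]:
    """Render a full dynamic force spectroscopy dataset with ground truth.

    Each ground-truth event becomes one retract curve (single specific
    event at the separation where the tether WLC reaches the rupture
    force). Returns (curves, truth) where truth has one row per event with
    its curve_id, velocity, rupture distance/force and loading rate.
    """
    rng = np.random.default_rng(config.seed)
    events = generate_dfs_events(config, rng)
    curves: list[ForceCurve] = []
    rows = []
    for i, row in enumerate(events.itertuples(index=False)):
        spec_v = replace(config.curve_spec, pulling_velocity=float(row.velocity))
        dist = extension_at_force(row.rupture_force, spec_v)
        curve_id = f"dfs-v{row.velocity:g}-{i:05d}"
        curve, _ = synthesize_retract_curve(
            [(dist, row.rupture_force)] if dist > 0.5 else [],
            spec_v, rng, curve_id=curve_id,
        )
        curves.append(curve)
        rows.append(
            {"curve_id": curve_id, "velocity": row.velocity,
             "distance": dist, "rupture_force": row.rupture_force,
             "loading_rate": row.loading_rate, "rendered": dist > 0.5}
        )
    return curves, pd.DataFrame(rows)


def generate_clamp_events(
    n: int,
    bond: BondModel,
    force_range: tuple[float, float] = (20.0, 120.0),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample ground-truth height-clamp events: uniform forces, Bell lifetimes.

    Returns a DataFrame with columns force_step (pN) and lifetime (s).
    """
    if rng is None:
        rng = np.random.default_rng()
    forces = rng.uniform(force_range[0], force_range[1], size=n)
    lifetimes = sample_bond_lifetime(forces, bond, rng)
    return pd.DataFrame({"force_step": forces, "lifetime": lifetimes})
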