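"""Kinetic model fitting for single-molecule bond rupture.

Three pieces of machinery:

* **Bell model** for constant-force (height-clamp) data: the lifetime of a
  slip bond under a constant pulling force F decays exponentially,

      t(F) = t0 · exp(−x_β F / k_B T),

  where t0 is the equilibrium lifetime and x_β the distance from the bound
  state to the transition barrier along the pulling coordinate. Individual
  (force, lifetime) events are binned by force and the binned means fitted
  in log-lifetime space, weighted by per-bin event counts.

* **Bell–Evans model** for force-ramp (dynamic force spectroscopy) data:
  under a constant loading rate LR the most probable rupture force grows
  logarithmically,

      F*(LR) = (k_B T / x_β) · ln( LR x_β / (k0 k_B T) ).

  Per pulling velocity, the most probable force and most probable loading
  rate are estimated by kernel density estimation and the resulting points
  fitted by Levenberg–Marquardt, weighted by per-velocity event counts.

* **Arrhenius conversion** of the zero-force off-rate k0 into a barrier
  height, ΔG = −k_B T · ln(τ_D k0), with τ_D = 1e-5 s the diffusive
  relaxation time; the error in ΔG is propagated to first order from the
  error in k0 (ΔG_err = k0_err / k0 in k_B T units).

Confidence intervals are 95%, from the fit covariance (Student-t with the
fit's residual degrees of freedom).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import gaussian_kde, t as student_t

from .core import (
    BellEvansFit,
    BellParams,
    ClampEvent,
    DfsPoint,
    DomainError,
    Environment,
    FitError,
    InsufficientDataError,
    thermal_energy,
)

DEFAULT_TAU_D = 1e-5  # s, diffusive relaxation time for the Arrhenius conversion


def bell_lifetime(force, t0: float, x_beta: float, env: Environment):
    """Bond lifetime t(F) = t0·exp(−x_β F/k_BT) for positive force magnitudes."""
    kbt = thermal_energy(env)
    return t0 * np.exp(-x_beta * np.asarray(force, dtype=float) / kbt)


def bell_evans_force(loading_rate, k0: float, x_beta: float, env: Environment):
    """Most probable rupture force F*(LR) of the Bell–Evans model."""
    kbt = thermal_energy(env)
    lr = np.asarray(loading_rate, dtype=float)
    return (kbt / x_beta) * np.log(lr * x_beta / (k0 * kbt))


@dataclass
class LifetimeBin:
    """One force bin of height-clamp events: mean force, mean lifetime, sd, count.

    ``force_width`` is the width of the force bin the events were pooled
    over; it feeds the finite-bin-width correction in :func:`fit_bell`
    (zero for bins that represent a single force).
    """

    mean_force: float  # pN
    mean_lifetime: float  # s
    lifetime_sd: float  # s
    n: int
    force_width: float = 0.0  # pN

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("n must be >= 1")
        if not (self.mean_lifetime > 0):
            raise DomainError("mean_lifetime must be > 0")
        if self.force_width < 0:
            raise DomainError("force_width must be >= 0")


def bin_lifetimes(events: Sequence[ClampEvent], n_bins: int = 8) -> list[LifetimeBin]:
    """Bin clamp events into equal-width force bins; empty bins are dropped."""
    if n_bins < 1:
        raise DomainError("n_bins must be >= 1")
    if len(events) < 2 * n_bins:
        raise InsufficientDataError(
            f"need at least {2 * n_bins} events for {n_bins} bins, got {len(events)}"
        )
    forces = np.array([e.force_step for e in events])
    lifetimes = np.array([e.lifetime for e in events])
    edges = np.linspace(forces.min(), forces.max(), n_bins + 1)
    width = float(edges[1] - edges[0])
    idx = np.clip(np.digitize(forces, edges[1:-1]), 0, n_bins - 1)
    bins = []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        bins.append(
            LifetimeBin(
                mean_force=float(forces[mask].mean()),
                mean_lifetime=float(lifetimes[mask].mean()),
                lifetime_sd=float(lifetimes[mask].std(ddof=1)) if mask.sum() > 1 else 0.0,
                n=int(mask.sum()),
                force_width=width,
            )
        )
    if len(bins) < min(2, n_bins):
        raise InsufficientDataError("fewer than 2 non-empty force bins")
    return bins


def fit_bell(bins: Sequence[LifetimeBin], env: Environment = Environment()) -> BellParams:
    """Fit the Bell model to binned lifetimes.

    Weighted least squares of ln(mean lifetime) against mean force, with
    weights proportional to the per-bin event counts. The model is linear
    in (ln t0, x_β), so the weighted normal equations solve it exactly.

    Because the lifetime decays exponentially across a force bin, the
    *bin-averaged* lifetime exceeds the lifetime at the bin's mean force
    by the factor sinh(a)/a with a = x_β·w/(2 k_BT) (w the bin width,
    forces ≈ uniform within the bin). That factor is divided out of each
    bin mean, iterating on the fitted x_β. A second, delta-method
    correction removes the small-sample bias of the log of a bin mean,
    E[ln t̄] ≈ ln E[t̄] − Var(t̄)/(2·E[t̄]²), using each bin's empirical
    lifetime sd and count. Both corrections vanish for zero-width,
    zero-sd bins, so exact inputs are recovered exactly.
    """
    if len(bins) < 3:
        raise InsufficientDataError("fit_bell needs at least 3 bins")
    kbt = thermal_energy(env)
    f = np.array([b.mean_force for b in bins])
    y0 = np.log([b.mean_lifetime for b in bins])
    w = np.array([b.n for b in bins], dtype=float)
    widths = np.array([b.force_width for b in bins])
    if np.ptp(f) == 0:
        raise FitError("x_beta unidentifiable: all bins at the same force")

    means = np.array([b.mean_lifetime for b in bins])
    sds = np.array([b.lifetime_sd for b in bins])
    # delta-method bias of ln(bin mean): -Var(mean)/(2 mean^2)
    log_bias = (sds**2 / w) / (2.0 * means**2)
    X = np.column_stack([np.ones_like(f), -f / kbt])
    sw = np.sqrt(w)
    coef = None
    y = y0 + log_bias
    for _ in range(4):  # iterate the bin-width correction on the fitted x_beta
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        a = np.maximum(coef[1], 0.0) * widths / (2.0 * kbt)
        ratio = np.where(a > 0, np.sinh(np.where(a > 0, a, 1.0)) / np.where(a > 0, a, 1.0), 1.0)
        y = y0 + log_bias - np.log(ratio)
    resid = y - X @ coef
    dof = len(bins) - 2
    if dof > 0:
        # cov scaled by the weighted residual variance (weights are relative)
        s2 = float(np.sum(w * resid**2)) / dof
        cov = s2 * np.linalg.inv((X * w[:, None]).T @ X)
        tcrit = float(student_t.ppf(0.975, dof))
        se = np.sqrt(np.diag(cov))
    else:
        tcrit, se = math.nan, np.array([math.nan, math.nan])

    ln_t0, x_beta = float(coef[0]), float(coef[1])
    if x_beta <= 0:
        raise FitError(f"fitted x_beta={x_beta:.3g} nm is non-positive; Bell model invalid")
    t0 = math.exp(ln_t0)
    return BellParams(
        t0=t0,
        x_beta=x_beta,
        t0_ci=t0 * tcrit * se[0],  # delta method on exp(ln t0)
        x_beta_ci=tcrit * se[1],
    )


def kde_mode(samples, bandwidth: float | None = None) -> float:
    """Mode of a Gaussian kernel density estimate (Silverman bandwidth).

    The density is evaluated on a 512-point grid spanning the data ± 3
    bandwidths. ``bandwidth`` (in data units) overrides Silverman's rule.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 5:
        raise InsufficientDataError(f"kde_mode needs >= 5 samples, got {x.size}")
    if np.ptp(x) == 0:
        return float(x[0])
    sd = x.std(ddof=1)
    bw_method = "silverman" if bandwidth is None else bandwidth / sd
    kde = gaussian_kde(x, bw_method=bw_method)
    h = kde.factor * sd
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, 512)
    return float(grid[np.argmax(kde(grid))])


def dfs_reduce(
    events: pd.DataFrame | Mapping[float, pd.DataFrame],
    min_events: int = 5,
) -> list[DfsPoint]:
    """Reduce per-velocity rupture events to most-probable (force, loading rate) points.

    ``events`` is a DataFrame with columns ``velocity``, ``rupture_force``
    and ``loading_rate`` (or a mapping velocity -> DataFrame). Events with
    undefined (NaN) loading rate are excluded. The most probable force is
    the KDE mode on the raw scale; the most probable loading rate is the
    KDE mode on the log scale (loading rates are strictly positive and
    right-skewed), transformed back.
    """
    if isinstance(events, pd.DataFrame):
        groups = {v: g for v, g in events.groupby("velocity")}
    else:
        groups = dict(events)
    points = []
    for velocity in sorted(groups):
        g = groups[velocity]
        ok = g.dropna(subset=["loading_rate"])
        ok = ok[ok["loading_rate"] > 0]
        if len(ok) < min_events:
            warnings.warn(
                f"velocity {velocity} µm/s: only {len(ok)} events with loading "
                f"rates (< {min_events}), group skipped",
                stacklevel=2,
            )
            continue
        mp_force = kde_mode(ok["rupture_force"].to_numpy())
        mp_lr = math.exp(kde_mode(np.log(ok["loading_rate"].to_numpy())))
        points.append(DfsPoint(velocity=float(velocity), mp_force=mp_force,
                               mp_loading_rate=mp_lr, n=len(ok)))
    return points


_K0_GRID = 10.0 ** np.arange(-4, 3.1, 1.0)
_XB_GRID = np.array([0.05, 0.15, 0.4, 1.0, 3.0, 10.0])


def fit_bell_evans(
    points: Sequence[DfsPoint],
    env: Environment = Environment(),
    tau_d: float = DEFAULT_TAU_D,
) -> BellEvansFit:
    """Weighted Levenberg–Marquardt fit of the Bell–Evans model to DFS points.

    Weights are proportional to per-velocity event counts. The fit is
    multi-started over a log-grid k0 ∈ [1e-4, 1e3] 1/s, x_β ∈ [0.05, 10] nm
    (in log parameters, for robustness across decades) and the best
    optimum refined with the parameters on their natural scale so that the
    covariance — and the 95% CI reported for k0 — is that of (k0, x_β)
    directly. ΔG is filled in via :func:`arrhenius_dg`.
    """
    if len(points) < 2:
        raise InsufficientDataError("fit_bell_evans needs at least 2 points")
    lr = np.array([p.mp_loading_rate for p in points])
    f = np.array([p.mp_force for p in points])
    n = np.array([p.n for p in points], dtype=float)
    if lr.max() / lr.min() < 3:
        raise InsufficientDataError("loading rates must span at least a factor 3")

    # weighted slope of F vs ln LR decides model validity and seeds x_beta
    x = np.log(lr)
    wm = n / n.sum()
    xb_ = x - np.sum(wm * x)
    slope = float(np.sum(wm * xb_ * f) / np.sum(wm * xb_**2))
    if slope <= 0:
        raise FitError("forces decrease with loading rate; Bell-Evans model invalid")

    kbt = thermal_energy(env)
    sw = np.sqrt(n / n.mean())

    def resid_log(theta):
        ln_k0, ln_xb = theta
        pred = (kbt / np.exp(ln_xb)) * (x + ln_xb - ln_k0 - math.log(kbt))
        return sw * (f - pred)

    best = None
    starts = [(math.log(k0), math.log(xb)) for k0 in _K0_GRID for xb in _XB_GRID]
    starts.insert(0, (math.log(max(lr.min() * kbt / slope * 1e-2, 1e-4)),
                      math.log(kbt / slope)))
    for theta0 in starts:
        try:
            sol = optimize.least_squares(resid_log, theta0, method="lm", xtol=1e-12)
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost - 1e-12):
            best = sol
    if best is None:
        raise FitError("Bell-Evans fit did not converge from any start")

    k0_hat, xb_hat = math.exp(best.x[0]), math.exp(best.x[1])

    def model(lr_, k0, x_beta):
        return (kbt / x_beta) * np.log(lr_ * x_beta / (k0 * kbt))

    dof = len(points) - 2
    k0_ci = xb_ci = math.nan
    if dof > 0:
        try:
            popt, pcov = optimize.curve_fit(
                model, lr, f, p0=(k0_hat, xb_hat),
                sigma=1.0 / sw, absolute_sigma=False, maxfev=10000,
            )
            if np.all(np.isfinite(pcov)) and popt[0] > 0 and popt[1] > 0:
                k0_hat, xb_hat = float(popt[0]), float(popt[1])
                tcrit = float(student_t.ppf(0.975, dof))
                se = np.sqrt(np.diag(pcov))
                k0_ci, xb_ci = tcrit * float(se[0]), tcrit * float(se[1])
        except Exception:
            pass  # keep the multi-start optimum; CIs stay undefined

    dg, dg_err = arrhenius_dg(k0_hat, k0_ci, tau_d, env)
    return BellEvansFit(
        k0=k0_hat, x_beta=xb_hat, delta_g=dg,
        k0_ci=k0_ci, x_beta_ci=xb_ci, delta_g_err=dg_err, tau_d=tau_d,
    )


def arrhenius_dg(
    k0: float,
    k0_err: float = math.nan,
    tau_d: float = DEFAULT_TAU_D,
    env: Environment = Environment(),
) -> tuple[float, float]:
    """Barrier height ΔG = −ln(τ_D·k0) in k_B T units, with propagated error.

    The first-order propagated error is |dΔG/dk0|·k0_err = k0_err/k0
    (also in k_B T). ``env`` is accepted for interface symmetry; in k_B T
    units the conversion is temperature-free.
    """
    if not (k0 > 0):
        raise DomainError("k0 must be > 0")
    if not (tau_d > 0):
        raise DomainError("tau_d must be > 0")
    dg = -math.log(tau_d * k0)
    dg_err = k0_err / k0 if not math.isnan(k0_err) else math.nan
    return dg, dg_err


def rate_to_lifetime(k0: float) -> float:
    """Equilibrium bond lifetime, the reciprocal of the zero-force off-rate."""
    if not (k0 > 0):
        raise DomainError("k0 must be > 0")
    return 1.0 / k0
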