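"""Comparison scenarios and the synthetic single-step growth experiment.

The distributed-latent-period model is compared against classical
approximations in which the latent period is a single number: the
distribution mean ("Fixed Mean"), its median ("Fixed Median"), or the time
of first observed lysis ("Fixed Early") — the time at which the number of
infective centers doubles in a single-step growth experiment, which is how
latent periods are classically read off bench assays.  Because the
earliest-lysing cells double the count before the average cell has lysed,
the Fixed Early value systematically underestimates the mean latent period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .distributions import (
    DiscretizedKernel,
    LatentDistribution,
    discretize_density,
    distribution_median,
)
from .kinetics import BurstProfile, KineticParameters, mean_burst_size
from .solvers import SimulationGrid, Trajectory

__all__ = [
    "ScenarioSpec",
    "LysisUndefinedError",
    "single_step_growth",
    "first_lysis_time",
    "fixed_latent_value",
    "default_single_step_grid",
]

SCENARIO_LABELS = (
    "DDDE-lognormal", "DDDE-normal", "DDDE-gamma",
    "Fixed-Mean", "Fixed-Median", "Fixed-Early", "TC",
)


class LysisUndefinedError(RuntimeError):
    """Infective centers never double (burst too small or decay too strong)."""


@dataclass(frozen=True)
class ScenarioSpec:
    """A named model variant to simulate for a given parameter set.

    ``dist`` is the reference latent-period distribution for DDDE labels and
    the source of the tau statistics for the fixed-delay and TC labels.
    """

    label: str
    dist: LatentDistribution
    burst_mode: str = "latent-dependent"

    def __post_init__(self) -> None:
        if self.label not in SCENARIO_LABELS:
            raise ValueError(
                f"unknown scenario {self.label!r}; expected one of {SCENARIO_LABELS}"
            )
        if self.burst_mode not in ("latent-dependent", "constant"):
            raise ValueError(f"unknown burst mode {self.burst_mode!r}")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "dist": self.dist.to_dict(),
            "burst_mode": self.burst_mode,
        }


def default_single_step_grid(
    dist_or_tau, dt: float | None = None
) -> SimulationGrid:
    """A grid covering one round of lysis for the given latent distribution."""
    if isinstance(dist_or_tau, LatentDistribution):
        if dist_or_tau.family == "point-mass":
            hi = dist_or_tau.tau_0 * 1.5
        else:
            hi = float(dist_or_tau.ppf(1.0 - 1e-6)) * 1.2
        ref = dist_or_tau.tau_0
    else:
        hi = float(dist_or_tau) * 1.5
        ref = float(dist_or_tau)
    if dt is None:
        dt = max(ref / 2000.0, 1e-5)
    n = max(int(math.ceil(hi / dt)), 10)
    return SimulationGrid(n * dt, dt)


def single_step_growth(
    params: KineticParameters,
    kernel_or_tau,
    burst: BurstProfile,
    grid: SimulationGrid,
    include_decay: bool = True,
) -> Trajectory:
    """Simulate a synchronized-infection, no-readsorption growth experiment.

    All inoculated phage are adsorbed at t = 0 (I(0) = P_init, U(0) = 0,
    P(0) = 0) and adsorption is switched off afterwards, so exactly one round
    of lysis is observed.  The infected cohort lyses according to the latent
    kernel; each lysis at tau_k releases beta_0(tau_k) phages per cell,
    attenuated by infected-cell survival.  Infective centers (plaque-forming
    units) are C(t) = P(t) + I(t).
    """
    dt = grid.dt
    if isinstance(kernel_or_tau, DiscretizedKernel):
        if not math.isclose(kernel_or_tau.dt, dt, rel_tol=1e-9):
            raise ValueError("kernel step does not match grid step")
        kernel = kernel_or_tau
    else:
        k0 = int(round(float(kernel_or_tau) / dt))
        kernel = DiscretizedKernel(
            dt, np.array([k0], dtype=np.int64), np.array([1.0])
        )

    delta_I = params.delta_I if include_decay else 0.0
    delta_P = params.delta_P if include_decay else 0.0
    C0 = params.P_init
    n = grid.n_steps
    times = grid.times

    taus = kernel.taus
    surv = np.exp(-delta_I * taus)
    beta0 = np.atleast_1d(
        mean_burst_size(taus, burst, params.r_beta, params.D, params.beta_tau50)
    )

    # surviving, not-yet-lysed cohort: I(t) = C0 e^{-dI t} (1 - F(t))
    lysed = np.zeros(n + 1)
    release = np.zeros(n + 1)
    in_range = kernel.offsets <= n
    np.add.at(lysed, kernel.offsets[in_range], kernel.weights[in_range])
    np.add.at(
        release,
        kernel.offsets[in_range],
        C0 * (beta0 * surv * kernel.weights)[in_range],
    )
    I = C0 * np.exp(-delta_I * times) * (1.0 - np.cumsum(lysed))
    I = np.clip(I, 0.0, None)

    # free phage: releases accumulate under exponential decay
    decay = max(1.0 - dt * delta_P, 0.0)
    P = lfilter([1.0], [1.0, -decay], release)
    U = np.zeros(n + 1)
    return Trajectory(times, U, I, P)


def first_lysis_time(trajectory: Trajectory) -> float:
    """Earliest time at which infective centers C = P + I reach 2 C(0).

    Linearly interpolated between the bracketing grid nodes.  Raises
    :class:`LysisUndefinedError` when doubling is never reached.
    """
    C = trajectory.P + trajectory.I
    C0 = C[0]
    if C0 <= 0:
        raise ValueError("single-step trajectory must start with C(0) > 0")
    target = 2.0 * C0
    above = np.nonzero(C >= target)[0]
    if len(above) == 0:
        raise LysisUndefinedError(
            f"infective centers peak at {np.max(C) / C0:.3g} x C0 < 2"
        )
    i = int(above[0])
    if i == 0:
        return float(trajectory.times[0])
    t0, t1 = trajectory.times[i - 1], trajectory.times[i]
    c0, c1 = C[i - 1], C[i]
    if c1 == c0:
        return float(t1)
    return float(t0 + (target - c0) / (c1 - c0) * (t1 - t0))


def fixed_latent_value(
    dist: LatentDistribution,
    mode: str,
    params: KineticParameters | None = None,
    burst: BurstProfile | None = None,
    dt: float | None = None,
) -> float:
    """The single latent period a fixed-delay approximation should use.

    mode 'mean' -> tau_0; 'median' -> distribution median; 'early' -> the
    infective-center doubling time of the distributed single-step experiment,
    which requires the kinetic parameters and the burst profile of the set.
    """
    if mode == "mean":
        return dist.tau_0
    if mode == "median":
        return distribution_median(dist)
    if mode == "early":
        if params is None or burst is None:
            raise ValueError("mode='early' requires params and burst")
        grid = default_single_step_grid(dist, dt=dt)
        kernel = discretize_density(dist, grid.dt)
        traj = single_step_growth(params, kernel, burst, grid)
        return first_lysis_time(traj)
    raise ValueError(f"unknown mode {mode!r}")
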