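"""Numerical integration of the three model structures.

* :func:`simulate_dde` — the classic fixed-latent-period delay model.
* :func:`simulate_ddde` — the distributed-delay model: the lysis terms are
  convolutions of the infection history phi(t) U(t) P(t) with the discretized
  latent-period kernel (survival- and burst-weighted).
* :func:`simulate_tc` — the transit-compartment chain, the ODE equivalent of
  an Erlang-distributed latent period with a constant mean burst size.

All three share the history convention that no phage existed before t = 0,
so every delayed term vanishes for arguments below zero.  The workhorse
stepper is forward Euler (compiled, see :mod:`phagedyn._core`) with a
step-halving convergence loop; an RK4 stepper with linear history
interpolation is available for cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _core
from .distributions import DiscretizedKernel
from .kinetics import BurstProfile, KineticParameters, mean_burst_size

__all__ = [
    "SimulationGrid",
    "Trajectory",
    "TransitConfig",
    "SimulationDivergedError",
    "ConvergenceResult",
    "simulate_dde",
    "simulate_ddde",
    "simulate_tc",
    "tc_config_from_distribution",
    "run_with_convergence",
    "auto_horizon",
]


class SimulationDivergedError(RuntimeError):
    """Integration produced a non-finite state."""

    def __init__(self, step: int, t: float):
        self.step = step
        self.t = t
        super().__init__(f"non-finite state at step {step} (t = {t:.4g} h)")


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform time grid; delays are integer multiples of dt."""

    t_end: float  # horizon (h)
    dt: float     # step (h)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("t_end and dt must be > 0")
        n = round(self.t_end / self.dt)
        if n < 1 or abs(n * self.dt - self.t_end) > 1e-9 * self.t_end:
            raise ValueError(
                f"t_end={self.t_end} is not an integer multiple of dt={self.dt}"
            )

    @property
    def n_steps(self) -> int:
        return round(self.t_end / self.dt)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt

    def halved(self) -> "SimulationGrid":
        return SimulationGrid(self.t_end, self.dt / 2.0)


@dataclass
class Trajectory:
    """Time grid plus the three concentration series."""

    times: np.ndarray
    U: np.ndarray
    I: np.ndarray
    P: np.ndarray
    n_floor: int = 0  # negative-state floorings during integration

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.U) == len(self.I) == len(self.P) == n):
            raise ValueError("series lengths must match the time grid")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def load(self, component: str) -> np.ndarray:
        """'bacterial' = U + I (CFU-like), 'viral' = P (PFU), 'U' = uninfected."""
        if component == "bacterial":
            return self.U + self.I
        if component == "viral":
            return self.P
        if component == "U":
            return self.U
        raise ValueError(f"unknown load component {component!r}")

    def downsample(self, stride: int) -> "Trajectory":
        s = slice(None, None, stride)
        return Trajectory(self.times[s], self.U[s], self.I[s], self.P[s],
                          self.n_floor)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.times, "U": self.U, "I": self.I, "P": self.P}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class TransitConfig:
    """Erlang chain: N stages, each left at rate k_tr (per hour)."""

    N: int
    k_tr: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.k_tr <= 0:
            raise ValueError("k_tr must be > 0")


def tc_config_from_distribution(tau_0: float, rsd_tau: float) -> TransitConfig:
    """Match an Erlang chain to (tau_0, rsd_tau): N = round(1/rsd^2), k_tr = N/tau_0.

    The chain's latency has mean N/k_tr = tau_0 and relative SD 1/sqrt(N).
    """
    if not (0.0 < rsd_tau <= 1.0):
        raise ValueError("rsd_tau must be in (0, 1]; rsd_tau = 0 has no finite chain")
    N = max(1, round(1.0 / rsd_tau**2))
    return TransitConfig(N=N, k_tr=N / tau_0)


def _finish(times, U, I, P, status, n_floor) -> Trajectory:
    if status != 0:
        raise SimulationDivergedError(status, times[min(status, len(times) - 1)])
    return Trajectory(times, U, I, P, n_floor=int(n_floor))


def _delay_weights(params: KineticParameters, kernel: DiscretizedKernel,
                   burst: BurstProfile) -> tuple[int, np.ndarray, np.ndarray]:
    """Survival- and burst-weighted convolution weights on the grid.

    Survival e^{-delta_I tau_k} is physical attrition of infected cells and is
    deliberately not renormalized; only the latent-period mass itself is.
    """
    taus = kernel.taus
    surv = np.exp(-params.delta_I * taus)
    wI = kernel.weights * surv
    beta0 = np.atleast_1d(
        mean_burst_size(taus, burst, params.r_beta, params.D, params.beta_tau50)
    )
    wP = beta0 * wI
    # densify: the compiled loop indexes delays contiguously from k_min
    k_min, k_max = kernel.k_min, kernel.k_max
    dense_I = np.zeros(k_max - k_min + 1)
    dense_P = np.zeros(k_max - k_min + 1)
    idx = kernel.offsets - k_min
    dense_I[idx] = wI
    dense_P[idx] = wP
    return k_min, dense_I, dense_P


def simulate_ddde(
    params: KineticParameters,
    kernel: DiscretizedKernel,
    burst: BurstProfile,
    grid: SimulationGrid,
    stepper: str = "euler",
) -> Trajectory:
    """Integrate the distributed-delay model on the grid."""
    if not math.isclose(kernel.dt, grid.dt, rel_tol=1e-9):
        raise ValueError(
            f"kernel step {kernel.dt} does not match grid step {grid.dt}"
        )
    k_min, wI, wP = _delay_weights(params, kernel, burst)
    return _run_delay(params, grid, k_min, wI, wP, stepper)


def simulate_dde(
    params: KineticParameters,
    tau_fixed: float,
    grid: SimulationGrid,
    stepper: str = "euler",
) -> Trajectory:
    """Integrate the classic fixed-latent-period model.

    The delay is rounded to the nearest grid node; the burst size is the
    population mean beta_0_mean, attenuated by infected-cell survival
    e^{-delta_I tau}.
    """
    if tau_fixed < 0:
        raise ValueError("tau_fixed must be >= 0")
    k0 = int(round(tau_fixed / grid.dt))
    tau_k = k0 * grid.dt
    surv = math.exp(-params.delta_I * tau_k)
    wI = np.array([surv])
    wP = np.array([params.beta_0_mean * surv])
    return _run_delay(params, grid, k0, wI, wP, stepper)


def _run_delay(params, grid, k_min, wI, wP, stepper) -> Trajectory:
    if stepper == "euler":
        U, I, P, status, n_floor = _core.euler_delay_loop(
            grid.n_steps, grid.dt,
            params.r_max, params.K_C, params.phi_max, params.P_50,
            params.delta_U, params.delta_I, params.delta_P,
            params.U_init, params.P_init,
            k_min, wI, wP,
        )
    elif stepper == "rk4":
        U, I, P, status, n_floor = _rk4_delay_loop(
            grid.n_steps, grid.dt, params, k_min, wI, wP
        )
    else:
        raise ValueError(f"unknown stepper {stepper!r}")
    return _finish(grid.times, U, I, P, status, n_floor)


def simulate_tc(
    params: KineticParameters,
    tc: TransitConfig,
    grid: SimulationGrid,
) -> Trajectory:
    """Integrate the transit-compartment model (constant burst beta_0_mean)."""
    U, Isum, P, status, n_floor = _core.euler_tc_loop(
        grid.n_steps, grid.dt,
        params.r_max, params.K_C, params.phi_max, params.P_50,
        params.delta_U, params.delta_I, params.delta_P,
        params.beta_0_mean, tc.N, tc.k_tr,
        params.U_init, params.P_init,
    )
    return _finish(grid.times, U, Isum, P, status, n_floor)


def _rk4_delay_loop(n_steps, dt, params: KineticParameters, k_min, wI, wP):
    """RK4 with linear interpolation of the stored history at half-steps.

    Delay terms for tau_k >= dt are read from the history of
    H(s) = phi(s) U(s) P(s); a tau = 0 kernel node (possible when
    tau_min = 0) contributes through the stage state itself.
    """
    U = np.zeros(n_steps + 1)
    I = np.zeros(n_steps + 1)
    P = np.zeros(n_steps + 1)
    H = np.zeros(n_steps + 1)
    U[0] = params.U_init
    P[0] = params.P_init
    ks = k_min + np.arange(len(wI))
    has_k0 = k_min == 0
    ks_hist = ks[1:] if has_k0 else ks
    wI_hist = wI[1:] if has_k0 else wI
    wP_hist = wP[1:] if has_k0 else wP
    wI0 = wI[0] if has_k0 else 0.0
    wP0 = wP[0] if has_k0 else 0.0

    def hist_at(fidx: np.ndarray, i: int) -> np.ndarray:
        # linear interpolation of H at fractional indices, zero before t=0
        lo = np.floor(fidx).astype(np.int64)
        frac = fidx - lo
        v_lo = np.where(lo >= 0, H[np.clip(lo, 0, i)], 0.0)
        v_hi = np.where(lo + 1 >= 0, H[np.clip(lo + 1, 0, i)], 0.0)
        return np.where(fidx >= 0, v_lo * (1 - frac) + v_hi * frac, 0.0)

    def deriv(u, v, p, fidx_now, i):
        phi = params.phi_max * params.P_50 / (params.P_50 + p)
        h = phi * u * p
        hdel = hist_at(fidx_now - ks_hist, i) if len(ks_hist) else 0.0
        s_out = float(np.dot(wI_hist, hdel)) if len(ks_hist) else 0.0
        s_src = float(np.dot(wP_hist, hdel)) if len(ks_hist) else 0.0
        s_out += wI0 * h
        s_src += wP0 * h
        r = params.r_max * (1.0 - (u + v) / params.K_C)
        du = r * u - params.delta_U * u - h
        dv = h - params.delta_I * v - s_out
        dp = s_src - params.delta_P * p - phi * (u + v) * p
        return du, dv, dp

    status = 0
    for i in range(n_steps):
        phi_i = params.phi_max * params.P_50 / (params.P_50 + P[i])
        H[i] = phi_i * U[i] * P[i]
        u, v, p = U[i], I[i], P[i]
        k1 = deriv(u, v, p, float(i), i)
        k2 = deriv(u + 0.5 * dt * k1[0], v + 0.5 * dt * k1[1],
                   p + 0.5 * dt * k1[2], i + 0.5, i)
        k3 = deriv(u + 0.5 * dt * k2[0], v + 0.5 * dt * k2[1],
                   p + 0.5 * dt * k2[2], i + 0.5, i)
        k4 = deriv(u + dt * k3[0], v + dt * k3[1], p + dt * k3[2],
                   float(i + 1), i)
        un = u + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        vn = v + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        pn = p + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        un, vn, pn = max(un, 0.0), max(vn, 0.0), max(pn, 0.0)
        if not (math.isfinite(un) and math.isfinite(vn) and math.isfinite(pn)):
            status = i + 1
            break
        U[i + 1], I[i + 1], P[i + 1] = un, vn, pn
    return U, I, P, status, 0


@dataclass
class ConvergenceResult:
    trajectory: Trajectory
    dt: float
    converged: bool
    n_halvings: int
    history: list = field(default_factory=list)  # (dt, bact_err_pct, viral_err_pct)


def run_with_convergence(
    sim_fn,
    t_end: float,
    dt_initial: float = 0.01,
    criterion: float = 1.0,
    max_halvings: int = 8,
    kernel_span: float | None = None,
    cost_budget: float = 4e10,
) -> ConvergenceResult:
    """Halve the step until both load profiles change by less than `criterion`.

    ``sim_fn(grid) -> Trajectory`` is re-run at dt, dt/2, ... and successive
    solutions are compared with the normalized area-between-curves metric on
    the bacterial (U + I) and viral (P) loads; both must fall below
    ``criterion`` (percent).  A diverged run at some dt is skipped and the
    halving continues.  Non-convergence (halvings or cost budget exhausted)
    is reported through the ``converged`` flag, never raised.

    ``kernel_span`` (hours) bounds the per-run cost estimate
    n_steps * kernel_length used against ``cost_budget``.
    """
    from .comparison import curve_error  # local to avoid import cycle at init

    prev: Trajectory | None = None
    last: Trajectory | None = None
    history: list = []
    dt = dt_initial
    n_halv = 0
    for level in range(max_halvings + 1):
        if kernel_span is not None:
            cost = (t_end / dt) * (max(kernel_span, dt) / dt)
            if cost > cost_budget:
                break
        try:
            traj = sim_fn(SimulationGrid(t_end, dt))
        except SimulationDivergedError:
            traj = None
        if traj is not None:
            if prev is not None:
                coarse = traj.downsample(round(prev.dt / traj.dt))
                be = curve_error(prev, coarse, "bacterial")
                ve = curve_error(prev, coarse, "viral")
                history.append((dt, be, ve))
                if be < criterion and ve < criterion:
                    return ConvergenceResult(traj, dt, True, n_halv, history)
            prev = traj
            last = traj
        if level == max_halvings:
            break
        dt /= 2.0
        n_halv += 1
    if last is None:
        raise SimulationDivergedError(0, 0.0)
    return ConvergenceResult(last, last.dt, False, n_halv, history)


def _settled(X: np.ndarray, rtol: float) -> bool:
    n = len(X)
    w = X[int(0.9 * n):]
    scale = float(np.max(w))
    if scale <= 1e-9 * max(float(np.max(X)), 1e-300):
        return True  # effectively extinct
    return float(np.max(w) - np.min(w)) <= rtol * scale


def auto_horizon(
    sim_fn,
    t_end0: float = 48.0,
    dt_probe: float = 0.01,
    settle_rtol: float = 1e-3,
    max_doublings: int = 2,
) -> float:
    """Pick a horizon capturing the post-lysis quasi-steady state.

    Probes at a coarse step and doubles t_end (at most ``max_doublings``
    times, i.e. up to 4x) while either load still changes by more than
    ``settle_rtol`` relative over the final 10% of the run.  If the probe
    itself diverges at every tried step the default horizon is returned; the
    convergence loop downstream will deal with the stiffness.
    """
    t_end = t_end0
    for k in range(max_doublings + 1):
        traj = None
        dt = dt_probe
        for _ in range(3):
            try:
                traj = sim_fn(SimulationGrid(t_end, dt))
                break
            except SimulationDivergedError:
                dt /= 2.0
        if traj is None:
            return t_end
        if _settled(traj.load("bacterial"), settle_rtol) and \
           _settled(traj.load("viral"), settle_rtol):
            return t_end
        if k < max_doublings:
            t_end *= 2.0
    return t_end
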