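"""Normalized area-between-curves error metric.

Two concentration-time profiles A and B are compared as

    Error (%) = 100 * 2 * int |X_A - X_B| dt / (int X_A dt + int X_B dt)

which is symmetric, scale-invariant and bounded in [0, 200] for nonnegative
curves (200 when one curve is identically zero).  The same metric drives the
step-halving convergence check of the solvers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CurveError", "auc", "curve_error", "trajectory_errors"]


@dataclass(frozen=True)
class CurveError:
    bacterial_error_pct: float
    viral_error_pct: float
    horizon: float


def auc(series, times) -> float:
    """Trapezoidal area under a nonnegative concentration series."""
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.shape != times.shape:
        raise ValueError("series and times must be aligned")
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(series, times))


def _common_prefix(traj_a, traj_b) -> int:
    """Number of shared grid nodes; the longer run is truncated."""
    n = min(len(traj_a.times), len(traj_b.times))
    if not np.allclose(traj_a.times[:n], traj_b.times[:n], rtol=1e-9, atol=1e-12):
        raise ValueError("trajectories are not on a common grid")
    return n


def curve_error(traj_a, traj_b, component: str = "bacterial") -> float:
    """Normalized area-between-curves error (percent) for one load component.

    ``component`` is 'bacterial' (U + I), 'viral' (P) or 'U'.  Both
    trajectories must share the grid over the common horizon.  If both
    curves are identically zero the error is defined as 0.
    """
    n = _common_prefix(traj_a, traj_b)
    t = traj_a.times[:n]
    xa = traj_a.load(component)[:n]
    xb = traj_b.load(component)[:n]
    denom = auc(xa, t) + auc(xb, t)
    if denom == 0.0:
        return 0.0
    return 100.0 * 2.0 * auc(np.abs(xa - xb), t) / denom


def trajectory_errors(traj_a, traj_b) -> CurveError:
    """Bacterial and viral errors over the common horizon."""
    n = _common_prefix(traj_a, traj_b)
    return CurveError(
        bacterial_error_pct=curve_error(traj_a, traj_b, "bacterial"),
        viral_error_pct=curve_error(traj_a, traj_b, "viral"),
        horizon=float(traj_a.times[n - 1]),
    )
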