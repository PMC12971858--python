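"""Monte Carlo comparison of model structures over randomized kinetics.

Parameter sets are drawn from literature-informed ranges (uniform or
log-uniform per parameter, with dependent bounds such as
P_50 >= r_max / phi_0 resolved against the already-drawn values).  For each
set and each requested scenario the trajectory is integrated with
step-halving convergence control on a shared horizon, and scenario pairs are
scored with the normalized area-between-curves metric on the bacterial
(U + I) and viral (P) loads.  Sets for which any scenario fails to converge
(or is infeasible, e.g. the truncated normal cannot reach the target width)
are replaced by a fresh draw from the same substream, so every cell ends up
with exactly ``n_sets`` converged rows.  Medians per (pair, rsd, load) are
the headline summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .comparison import trajectory_errors
from .distributions import (
    InfeasibleDistributionError,
    LatentDistribution,
    build_distribution,
    discretize_density,
)
from .kinetics import (
    BurstProfile,
    InvalidParameterSetError,
    KineticParameters,
    normalize_beta_max,
)
from .scenarios import (
    LysisUndefinedError,
    ScenarioSpec,
    fixed_latent_value,
)
from .solvers import (
    SimulationDivergedError,
    Trajectory,
    auto_horizon,
    run_with_convergence,
    simulate_dde,
    simulate_ddde,
    simulate_tc,
    tc_config_from_distribution,
)

__all__ = [
    "RangeSpec",
    "ParameterRanges",
    "ParameterSetDraw",
    "StudyResult",
    "CellBudgetExhaustedError",
    "sample_parameter_set",
    "run_cell",
    "run_comparison_study",
    "compile_summary",
    "median_ci",
]

_LABEL_FAMILY = {
    "DDDE-lognormal": "lognormal",
    "DDDE-normal": "truncated-normal",
    "DDDE-gamma": "gamma",
}


class CellBudgetExhaustedError(RuntimeError):
    """Too many resamples; the cell cannot be filled."""


@dataclass(frozen=True)
class RangeSpec:
    """One sampled parameter: bounds (possibly depending on earlier draws)
    and sampling scale."""

    low: float | Callable[[dict], float]
    high: float | Callable[[dict], float]
    scale: str = "uniform"  # "uniform" | "log-uniform"

    def draw(self, rng: np.random.Generator, drawn: dict) -> float:
        lo = self.low(drawn) if callable(self.low) else self.low
        hi = self.high(drawn) if callable(self.high) else self.high
        if not lo < hi:
            if math.isclose(lo, hi, rel_tol=1e-12, abs_tol=1e-300):
                return float(lo)
            raise ValueError(f"empty range [{lo}, {hi}]")
        if self.scale == "uniform":
            return float(rng.uniform(lo, hi))
        if self.scale == "log-uniform":
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        raise ValueError(f"unknown scale {self.scale!r}")


@dataclass(frozen=True)
class ParameterRanges:
    """Sampling ranges; insertion order is the dependency order."""

    specs: dict = field(default_factory=dict)
    sampled_burst_quantity: str = "beta_0_mean"  # or "beta_max"

    @classmethod
    def default(cls, sampled_burst_quantity: str = "beta_0_mean") -> "ParameterRanges":
        specs = {
            "r_max": RangeSpec(0.5, 2.5),
            "K_C": RangeSpec(1e8, 1e10, "log-uniform"),
            "phi_max": RangeSpec(1e-9, 1e-7, "log-uniform"),
            "delta_U": RangeSpec(0.1, 0.25),
            "delta_I": RangeSpec(0.1, 0.25),
            "delta_P": RangeSpec(0.05, 0.15),
            "tau_0": RangeSpec(0.25, 3.0),
            # phage cannot lyse instantly, but first lysis precedes tau_0
            "tau_min": RangeSpec(0.0, lambda d: d["tau_0"] / 2.0),
            "beta_0_mean": RangeSpec(10.0, 500.0, "log-uniform"),
            "r_beta": RangeSpec(1.0, 10.0),
            # replication must start before lysis
            "D": RangeSpec(0.0, lambda d: d["tau_0"]),
            # half-max latent period within the allowed latent periods
            "beta_tau50": RangeSpec(lambda d: d["D"], 3.0),
            # bactericidal effect stronger than natural growth at saturation
            "P_50": RangeSpec(
                lambda d: d["r_max"] / d["phi_max"], 1e10, "log-uniform"
            ),
            # inoculum below the net proliferation ceiling
            "U_init": RangeSpec(
                1e3,
                lambda d: d["K_C"] * (1.0 - d["delta_U"] / d["r_max"]),
                "log-uniform",
            ),
            "P_init": RangeSpec(1e3, 1e9, "log-uniform"),
        }
        return cls(specs=specs, sampled_burst_quantity=sampled_burst_quantity)


@dataclass(frozen=True)
class ParameterSetDraw:
    """One sampled parameter set: kinetics plus the latent-period targets."""

    kinetics: KineticParameters
    tau_0: float
    tau_min: float


def sample_parameter_set(
    ranges: ParameterRanges, rng: np.random.Generator
) -> ParameterSetDraw:
    """Draw one parameter set; dependent bounds use already-drawn values."""
    drawn: dict = {}
    for name, spec in ranges.specs.items():
        drawn[name] = spec.draw(rng, drawn)
    tau_0 = drawn.pop("tau_0")
    tau_min = drawn.pop("tau_min")
    kin = KineticParameters(**drawn)
    return ParameterSetDraw(kin, tau_0, tau_min)


# ---------------------------------------------------------------------------
# scenario realization


@dataclass
class _Runnable:
    label: str
    sim_fn: Callable  # grid -> Trajectory
    kernel_span: float | None  # convolution span (h), None for O(1)-delay models


def _realize_scenarios(
    labels: Sequence[str],
    draw: ParameterSetDraw,
    rsd_tau: float,
    reference_family: str = "lognormal",
    burst_mode: str = "latent-dependent",
) -> list[_Runnable]:
    """Build per-set runnable scenarios sharing the sampled kinetics.

    Fixed-delay and TC labels take their tau statistics from the
    ``reference_family`` distribution.  Raises the resample-triggering
    exceptions on infeasible draws.
    """
    kin = draw.kinetics
    dists: dict[str, LatentDistribution] = {}
    bursts: dict[str, BurstProfile] = {}

    def dist_for(family: str) -> LatentDistribution:
        if family not in dists:
            dists[family] = build_distribution(
                family, draw.tau_0, rsd_tau, draw.tau_min
            )
        return dists[family]

    def burst_for(family: str) -> BurstProfile:
        if burst_mode == "constant":
            return BurstProfile("constant", kin.beta_0_mean)
        if family not in bursts:
            bmax = normalize_beta_max(
                kin.beta_0_mean, dist_for(family), kin.r_beta, kin.D,
                kin.beta_tau50,
            )
            bursts[family] = BurstProfile(
                "latent-dependent", kin.beta_0_mean, bmax
            )
        return bursts[family]

    out: list[_Runnable] = []
    for label in labels:
        if label in _LABEL_FAMILY:
            family = _LABEL_FAMILY[label]
            dist = dist_for(family)
            burst = burst_for(family)
            span = (
                float(dist.ppf(1.0 - 1e-6)) - dist.tau_min
                if dist.family != "point-mass" else 0.0
            )

            def sim_ddde(grid, _d=dist, _b=burst):
                kernel = discretize_density(_d, grid.dt)
                return simulate_ddde(kin, kernel, _b, grid)

            out.append(_Runnable(label, sim_ddde, span))
        elif label in ("Fixed-Mean", "Fixed-Median", "Fixed-Early"):
            ref = dist_for(reference_family)
            mode = label.split("-")[1].lower()
            tau_fixed = fixed_latent_value(
                ref, mode, kin, burst_for(reference_family)
            )

            def sim_dde(grid, _tau=tau_fixed):
                return simulate_dde(kin, _tau, grid)

            out.append(_Runnable(label, sim_dde, None))
        elif label == "TC":
            tc = tc_config_from_distribution(draw.tau_0, rsd_tau)

            def sim_tc(grid, _tc=tc):
                return simulate_tc(kin, _tc, grid)

            out.append(_Runnable(label, sim_tc, None))
        else:
            raise ValueError(f"unknown scenario label {label!r}")
    return out


_RESAMPLE_EXC = (
    InfeasibleDistributionError,
    InvalidParameterSetError,
    LysisUndefinedError,
    SimulationDivergedError,
)


class _NotConverged(RuntimeError):
    pass


def _evaluate_draw(
    labels, pairs, draw, rsd_tau, reference_family, burst_mode,
    dt_initial, criterion, max_halvings, cost_budget,
):
    runnables = _realize_scenarios(
        labels, draw, rsd_tau, reference_family, burst_mode
    )
    t_end = auto_horizon(runnables[0].sim_fn, dt_probe=dt_initial)
    trajs: dict[str, Trajectory] = {}
    dts: dict[str, float] = {}
    for rn in runnables:
        res = run_with_convergence(
            rn.sim_fn, t_end, dt_initial=dt_initial, criterion=criterion,
            max_halvings=max_halvings, kernel_span=rn.kernel_span,
            cost_budget=cost_budget,
        )
        if not res.converged:
            raise _NotConverged(rn.label)
        trajs[rn.label] = res.trajectory
        dts[rn.label] = res.dt
    rows = []
    for a, b in pairs:
        ta, tb = trajs[a], trajs[b]
        # compare on the coarser of the two converged grids (nested halvings)
        if ta.dt > tb.dt:
            tb = tb.downsample(round(ta.dt / tb.dt))
        elif tb.dt > ta.dt:
            ta = ta.downsample(round(tb.dt / ta.dt))
        err = trajectory_errors(ta, tb)
        rows.append((f"{a} vs {b}", err.bacterial_error_pct,
                     err.viral_error_pct, err.horizon))
    return rows, dts


def run_cell(
    labels: Sequence[str],
    pairs: Sequence[tuple[str, str]],
    rsd_tau: float,
    n_sets: int,
    ranges: ParameterRanges | None = None,
    master_seed: int = 120659,
    cell_key: int = 0,
    reference_family: str = "lognormal",
    burst_mode: str = "latent-dependent",
    dt_initial: float = 0.01,
    criterion: float = 1.0,
    max_halvings: int = 8,
    cost_budget: float = 4e10,
    resample_factor: int = 10,
) -> pd.DataFrame:
    """Fill one Monte Carlo cell: ``n_sets`` converged parameter sets at a
    fixed rsd, scored on every requested scenario pair.

    Substream j of set j is derived deterministically from
    (master_seed, cell_key, j); resamples continue the same substream, so a
    run is bit-reproducible for a given master seed.
    """
    if ranges is None:
        ranges = ParameterRanges.default()
    records = []
    for j in range(n_sets):
        ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(cell_key, j))
        rng = np.random.default_rng(ss)
        resamples = 0
        while True:
            draw = None
            try:
                draw = sample_parameter_set(ranges, rng)
                rows, dts = _evaluate_draw(
                    labels, pairs, draw, rsd_tau, reference_family,
                    burst_mode, dt_initial, criterion, max_halvings,
                    cost_budget,
                )
                break
            except (_NotConverged, *_RESAMPLE_EXC):
                resamples += 1
                if resamples > resample_factor:
                    raise CellBudgetExhaustedError(
                        f"set {j} at rsd={rsd_tau}: resample budget "
                        f"({resample_factor}) exhausted"
                    )
        for pair_label, be, ve, horizon in rows:
            records.append({
                "set_id": j,
                "master_seed": master_seed,
                "rsd_tau": rsd_tau,
                "pair": pair_label,
                "bacterial_error_pct": be,
                "viral_error_pct": ve,
                "horizon_h": horizon,
                "converged": True,
                "resamples": resamples,
                "tau_0": draw.tau_0,
                "tau_min": draw.tau_min,
            })
    return pd.DataFrame.from_records(records)


@dataclass
class StudyResult:
    """Rows of pairwise errors plus the per-cell median summary."""

    records: pd.DataFrame
    summary: pd.DataFrame
    master_seed: int
    n_sets: int


def compile_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Long-format median/IQR table per (pair, rsd, load)."""
    if records.empty:
        raise ValueError("no records to summarize")
    rows = []
    for (pair, rsd), grp in records.groupby(["pair", "rsd_tau"], sort=True):
        for load, col in (
            ("bacterial", "bacterial_error_pct"),
            ("viral", "viral_error_pct"),
        ):
            vals = grp.loc[grp["converged"], col].to_numpy()
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({
                "pair": pair,
                "rsd_tau": rsd,
                "load": load,
                "median_error_pct": med,
                "iqr_error_pct": q3 - q1,
                "n": len(vals),
            })
    return pd.DataFrame(rows)


def run_comparison_study(
    pair: tuple[ScenarioSpec | str, ScenarioSpec | str],
    rsd_grid: Sequence[float],
    n_sets: int,
    ranges: ParameterRanges | None = None,
    master_seed: int = 120659,
    **cell_kwargs,
) -> StudyResult:
    """Compare one scenario pair over an rsd grid, n_sets draws per cell."""
    labels = tuple(
        s.label if isinstance(s, ScenarioSpec) else s for s in pair
    )
    frames = []
    for idx, rsd in enumerate(rsd_grid):
        frames.append(run_cell(
            labels, [labels], rsd, n_sets, ranges=ranges,
            master_seed=master_seed, cell_key=idx, **cell_kwargs,
        ))
    records = pd.concat(frames, ignore_index=True)
    return StudyResult(records, compile_summary(records), master_seed, n_sets)


def median_ci(
    values,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Median with a bootstrap (1 - alpha) confidence interval."""
    vals = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    meds = np.median(
        rng.choice(vals, size=(n_boot, len(vals)), replace=True), axis=1
    )
    lo, hi = np.percentile(meds, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(np.median(vals)), float(lo), float(hi)
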