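"""Latent-period distributions: construction, moment matching, discretization.

Single-cell studies show the time between phage infection and lysis varies
between cells.  Here that latent period is a random variable with target mean
``tau_0``, target relative standard deviation ``rsd_tau`` and a hard minimum
``tau_min`` (a phage cannot lyse its host instantly).  Three families are
supported plus a degenerate point mass:

* ``truncated-normal`` — a normal truncated to [tau_min, inf); the parent
  mean/SD are solved by damped Newton-Raphson so the *truncated* moments hit
  the targets exactly.
* ``lognormal`` and ``gamma`` — shifted by tau_min, with the shifted
  variable's mean/SD matched in closed form.
* ``point-mass`` — all mass at tau_0 (rsd_tau = 0).

For the delay solvers the density is discretized onto the simulation grid as
a probability-mass kernel (CDF differences over midpoint bins, renormalized).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import log_ndtr

__all__ = [
    "LatentDistribution",
    "DiscretizedKernel",
    "InfeasibleDistributionError",
    "build_distribution",
    "solve_truncated_normal_params",
    "discretize_density",
    "distribution_median",
]

FAMILIES = ("truncated-normal", "lognormal", "gamma", "point-mass")


class InfeasibleDistributionError(ValueError):
    """Target moments unattainable for the requested family/truncation."""


@dataclass(frozen=True)
class LatentDistribution:
    family: str
    tau_0: float        # realized mean (h)
    rsd_tau: float      # realized relative SD, sd/tau_0
    tau_min: float      # minimal latent period (h)
    internal_params: dict = field(compare=False)
    _frozen: object = field(default=None, compare=False, repr=False)

    @property
    def sd(self) -> float:
        return self.rsd_tau * self.tau_0

    def pdf(self, tau):
        if self.family == "point-mass":
            raise ValueError("point-mass distribution has no density")
        return self._frozen.pdf(tau)

    def cdf(self, tau):
        if self.family == "point-mass":
            return (np.asarray(tau, dtype=float) >= self.tau_0).astype(float)
        return self._frozen.cdf(tau)

    def ppf(self, q):
        if self.family == "point-mass":
            return np.full_like(np.asarray(q, dtype=float), self.tau_0) \
                if np.ndim(q) else self.tau_0
        return self._frozen.ppf(q)

    def rvs(self, size, rng):
        if self.family == "point-mass":
            return np.full(size, self.tau_0)
        return self._frozen.rvs(size=size, random_state=rng)

    def median(self) -> float:
        return distribution_median(self)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "tau_0": self.tau_0,
            "rsd_tau": self.rsd_tau,
            "tau_min": self.tau_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LatentDistribution":
        return build_distribution(
            d["family"], float(d["tau_0"]), float(d["rsd_tau"]),
            float(d.get("tau_min", 0.0)),
        )


def _truncnorm_moments(mu: float, sigma: float, a: float) -> tuple[float, float]:
    """Mean and SD of N(mu, sigma^2) truncated to [a, inf).

    Uses the Mills-ratio form lambda = phi(alpha)/(1-Phi(alpha)) evaluated in
    log space so it stays accurate deep into the tail.
    """
    alpha = (a - mu) / sigma
    lam = math.exp(stats.norm.logpdf(alpha) - log_ndtr(-alpha))
    mean = mu + sigma * lam
    var_factor = 1.0 + alpha * lam - lam * lam
    var_factor = max(var_factor, 1e-300)
    return mean, sigma * math.sqrt(var_factor)


def solve_truncated_normal_params(
    tau_0: float,
    sd: float,
    tau_min: float,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Parent (mu, sigma) of a normal truncated to [tau_min, inf) with the
    requested truncated mean and SD.

    Damped Newton-Raphson on the two moment residuals, iterating in
    (mu, log sigma) from the naive start (tau_0, sd).  One-sided truncation
    bounds sd below tau_0 - tau_min; infeasible targets raise with the final
    residual.
    """
    if not (tau_0 > tau_min):
        raise InfeasibleDistributionError("tau_0 must exceed tau_min")
    if sd <= 0:
        raise InfeasibleDistributionError("sd must be > 0")
    if sd >= 0.995 * (tau_0 - tau_min):
        # one-sided truncated normal has sd < mean - bound (exponential limit)
        raise InfeasibleDistributionError(
            f"sd={sd:.4g} unattainable above truncation bound: requires "
            f"sd < tau_0 - tau_min = {tau_0 - tau_min:.4g}"
        )

    def residual(x):
        mu, logsig = x
        m, s = _truncnorm_moments(mu, math.exp(logsig), tau_min)
        return np.array([(m - tau_0) / tau_0, (s - sd) / sd])

    x = np.array([tau_0, math.log(sd)])
    f = residual(x)
    for _ in range(max_iter):
        if np.max(np.abs(f)) < tol:
            break
        # finite-difference Jacobian of the (analytic) moment residuals
        J = np.empty((2, 2))
        for j in range(2):
            h = 1e-7 * max(1.0, abs(x[j]))
            xp = x.copy()
            xp[j] += h
            J[:, j] = (residual(xp) - f) / h
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError as exc:
            raise InfeasibleDistributionError(
                f"singular Jacobian, residual {np.max(np.abs(f)):.2e}"
            ) from exc
        lam = 1.0
        for _ in range(40):
            x_new = x + lam * step
            f_new = residual(x_new)
            if np.linalg.norm(f_new) < np.linalg.norm(f):
                break
            lam *= 0.5
        else:
            raise InfeasibleDistributionError(
                f"Newton-Raphson stalled, residual {np.max(np.abs(f)):.2e}"
            )
        x, f = x_new, f_new
    else:
        raise InfeasibleDistributionError(
            f"no convergence in {max_iter} iterations, "
            f"residual {np.max(np.abs(f)):.2e}"
        )
    return float(x[0]), float(math.exp(x[1]))


def build_distribution(
    family: str,
    tau_0: float,
    rsd_tau: float,
    tau_min: float = 0.0,
) -> LatentDistribution:
    """Build a latent-period distribution matching (tau_0, rsd_tau, tau_min).

    rsd_tau = 0 always yields the point mass at tau_0.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if tau_min < 0 or not (tau_0 > tau_min):
        raise InfeasibleDistributionError(
            f"need tau_0 > tau_min >= 0, got tau_0={tau_0}, tau_min={tau_min}"
        )
    if not (0.0 <= rsd_tau < 1.0):
        raise InfeasibleDistributionError(f"rsd_tau must be in [0, 1), got {rsd_tau}")

    if rsd_tau == 0.0 or family == "point-mass":
        return LatentDistribution(
            "point-mass", tau_0, 0.0, tau_min, internal_params={}
        )

    m = tau_0 - tau_min   # mean of the shifted variable
    s = rsd_tau * tau_0

    if family == "gamma":
        shape = (m / s) ** 2
        scale = s * s / m
        frozen = stats.gamma(shape, loc=tau_min, scale=scale)
        params = {"shape": shape, "scale": scale}
    elif family == "lognormal":
        sigma2 = math.log1p((s / m) ** 2)
        sigma = math.sqrt(sigma2)
        mu = math.log(m) - sigma2 / 2.0
        frozen = stats.lognorm(s=sigma, loc=tau_min, scale=math.exp(mu))
        params = {"mu": mu, "sigma": sigma}
    else:  # truncated-normal
        mu, sigma = solve_truncated_normal_params(tau_0, s, tau_min)
        a = (tau_min - mu) / sigma
        frozen = stats.truncnorm(a, np.inf, loc=mu, scale=sigma)
        params = {"parent_mean": mu, "parent_sd": sigma}

    return LatentDistribution(
        family, tau_0, rsd_tau, tau_min, internal_params=params, _frozen=frozen
    )


def distribution_median(dist: LatentDistribution) -> float:
    """0.5 quantile of the (shifted/truncated) latent-period distribution."""
    if dist.family == "point-mass":
        return dist.tau_0
    return float(dist._frozen.median())


@dataclass(frozen=True)
class DiscretizedKernel:
    """Grid-aligned probability mass approximating the latent-period density.

    ``weights[j]`` is the mass at delay ``offsets[j]`` steps, i.e. at
    tau = offsets[j] * dt.  Offsets are contiguous; weights sum to 1.
    """

    dt: float
    offsets: np.ndarray   # int, contiguous k_min..k_max
    weights: np.ndarray   # float, sum 1

    @property
    def k_min(self) -> int:
        return int(self.offsets[0])

    @property
    def k_max(self) -> int:
        return int(self.offsets[-1])

    @property
    def taus(self) -> np.ndarray:
        return self.offsets * self.dt

    def mean(self) -> float:
        return float(np.dot(self.weights, self.taus))


def discretize_density(
    dist: LatentDistribution,
    dt: float,
    tail_quantile: float = 1.0 - 1e-6,
) -> DiscretizedKernel:
    """Discretize a latent-period density onto a grid of step dt.

    Mass at node tau_k = k*dt is the CDF difference over
    [tau_k - dt/2, tau_k + dt/2] (clipped at tau_min), renormalized to sum 1.
    Nodes run from the first grid point at or above tau_min to the
    tail_quantile point of the distribution.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not (0.0 < tail_quantile < 1.0):
        raise ValueError("tail_quantile must be in (0, 1)")

    if dist.family == "point-mass":
        k0 = int(round(dist.tau_0 / dt))
        return DiscretizedKernel(
            dt, np.array([k0], dtype=np.int64), np.array([1.0])
        )

    if dt > dist.sd:
        warnings.warn(
            f"grid step dt={dt} exceeds the latent-period SD {dist.sd:.4g}; "
            "the discretized kernel is near-degenerate",
            RuntimeWarning,
            stacklevel=2,
        )

    k_min = int(math.ceil(dist.tau_min / dt - 1e-9))
    hi = float(dist.ppf(tail_quantile))
    k_max = max(int(math.ceil(hi / dt)), k_min)
    ks = np.arange(k_min, k_max + 1, dtype=np.int64)
    edges = np.concatenate([(ks - 0.5) * dt, [(k_max + 0.5) * dt]])
    edges = np.clip(edges, dist.tau_min, None)
    cdf = np.asarray(dist.cdf(edges), dtype=float)
    w = np.diff(cdf)
    total = w.sum()
    if total <= 0:
        raise ValueError("discretization captured no probability mass")
    w /= total
    return DiscretizedKernel(dt, ks, w)
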