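"""Rate laws of the phage-bacteria population model.

The model tracks uninfected bacteria U, infected bacteria I and free phage P.
Bacteria grow logistically toward a ceiling concentration, phage adsorb to
bacteria with a rate that saturates in phage concentration, and each lysing
cell releases a burst of progeny whose mean size depends on how long the cell
incubated the phage (the latent period tau).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from typing import TYPE_CHECKING

import numpy as np
from scipy import integrate

if TYPE_CHECKING:  # pragma: no cover
    from .distributions import LatentDistribution

__all__ = [
    "KineticParameters",
    "BurstProfile",
    "InvalidParameterSetError",
    "logistic_growth_rate",
    "saturable_adsorption_rate",
    "burst_size_shape",
    "mean_burst_size",
    "normalize_beta_max",
]


class InvalidParameterSetError(ValueError):
    """A kinetic/distribution combination that cannot define a valid model."""


@dataclass(frozen=True)
class KineticParameters:
    """Population-level rate constants and inoculums.

    Units: rates per hour, concentrations per mL, times in hours,
    burst sizes in phage per bacterium.
    """

    r_max: float        # maximal bacterial growth rate (/h)
    K_C: float          # ceiling (carrying) bacterial concentration (bact/mL)
    phi_max: float      # maximal adsorption rate (mL/cell/h)
    P_50: float         # phage conc. at half-maximal adsorption (phage/mL)
    delta_U: float      # decay rate of uninfected bacteria (/h)
    delta_I: float      # decay rate of infected bacteria (/h)
    delta_P: float      # decay rate of free phage (/h)
    beta_0_mean: float  # population mean burst size (phage/bact)
    r_beta: float       # intracellular phage replication rate (/h)
    D: float            # delay below which burst size is zero (h)
    beta_tau50: float   # latent period at half-maximal burst size (h)
    U_init: float       # bacterial inoculum (bact/mL)
    P_init: float       # phage inoculum (phage/mL)

    def __post_init__(self) -> None:
        vals = asdict(self)
        for name, v in vals.items():
            if not math.isfinite(v):
                raise InvalidParameterSetError(f"{name} must be finite, got {v}")
            if v < 0:
                raise InvalidParameterSetError(f"{name} must be nonnegative, got {v}")
        if self.K_C <= 0:
            raise InvalidParameterSetError("K_C must be > 0")
        if self.P_50 <= 0:
            raise InvalidParameterSetError("P_50 must be > 0")
        if self.beta_tau50 < self.D:
            raise InvalidParameterSetError("beta_tau50 must be >= D")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        return cls(**{k: float(v) for k, v in d.items()})

    def with_(self, **kwargs) -> "KineticParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class BurstProfile:
    """Mean burst size as a function of the latent period.

    In ``latent-dependent`` mode the mean burst size of a cell lysing after a
    latent period tau follows a saturating sigmoid in tau, scaled by
    ``beta_max`` (obtained from :func:`normalize_beta_max` so that the
    population average equals ``beta_0_mean``).  In ``constant`` mode every
    cell releases ``beta_0_mean`` phages on average regardless of tau, which
    is the assumption built into the transit-compartment model.
    """

    mode: str                    # "latent-dependent" | "constant"
    beta_0_mean: float
    beta_max: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("latent-dependent", "constant"):
            raise ValueError(f"unknown burst mode {self.mode!r}")
        if self.mode == "latent-dependent" and (
            self.beta_max is None or self.beta_max <= 0
        ):
            raise ValueError("latent-dependent mode requires beta_max > 0")


def _check_finite(**kwargs) -> None:
    for name, v in kwargs.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} must be finite")


def logistic_growth_rate(r_max: float, K_C: float, U, I):
    """Per-capita logistic growth rate r_max * (1 - (U + I) / K_C).

    Counts infected cells toward the niche occupancy; may be negative when
    the total load exceeds the ceiling K_C.
    """
    _check_finite(r_max=r_max, K_C=K_C, U=U, I=I)
    if K_C <= 0:
        raise ValueError("K_C must be > 0")
    return r_max * (1.0 - (np.asarray(U) + np.asarray(I)) / K_C)


def saturable_adsorption_rate(phi_max: float, P_50: float, P):
    """Adsorption rate phi_max * P_50 / (P_50 + P), saturating in phage load."""
    _check_finite(phi_max=phi_max, P_50=P_50, P=P)
    if P_50 <= 0:
        raise ValueError("P_50 must be > 0")
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("P must be nonnegative")
    return phi_max * P_50 / (P_50 + P)


def burst_size_shape(tau, r_beta: float, D: float, beta_tau50: float):
    """Normalized burst-size sigmoid g(tau) in [0, 1).

    g(tau) = (e^{r_beta (tau-D)} - 1) / (e^{r_beta (btau50-D)} + e^{r_beta (tau-D)} - 2)

    with g(tau) = 0 for tau <= D.  Evaluated in a form that saturates to 1
    instead of overflowing for large r_beta * tau.
    """
    tau = np.asarray(tau, dtype=float)
    a = r_beta * (tau - D)
    b = r_beta * (beta_tau50 - D)
    out = np.zeros_like(a)
    eb = math.exp(b)  # b <= r_beta * beta_tau50, bounded in practice

    small = (a > 0) & (a < 50.0)
    if np.any(small):
        ea = np.exp(a[small])
        out[small] = (ea - 1.0) / (eb + ea - 2.0)
    big = a >= 50.0
    if np.any(big):
        # divide numerator and denominator by e^a
        ema = np.exp(-a[big])
        out[big] = (1.0 - ema) / ((eb - 2.0) * ema + 1.0)
    return out if out.ndim else float(out)


def mean_burst_size(
    tau,
    burst: BurstProfile,
    r_beta: float,
    D: float,
    beta_tau50: float,
):
    """Mean burst size beta_0(tau) under a burst profile.

    Zero for tau <= D in latent-dependent mode; beta_0_mean everywhere in
    constant mode.
    """
    if burst.mode == "constant":
        return np.full_like(np.asarray(tau, dtype=float), burst.beta_0_mean) \
            if np.ndim(tau) else burst.beta_0_mean
    g = burst_size_shape(tau, r_beta, D, beta_tau50)
    return burst.beta_max * g


def normalize_beta_max(
    beta_0_mean: float,
    dist: "LatentDistribution",
    r_beta: float,
    D: float,
    beta_tau50: float,
    *,
    tail_quantile: float = 1.0 - 1e-8,
    epsrel: float = 1e-9,
) -> float:
    """Scale factor beta_max so the population mean burst size is beta_0_mean.

    Solves beta_max = beta_0_mean / E_f[g(tau)] where g is the normalized
    burst sigmoid and f the latent-period density, by adaptive quadrature
    over [tau_min, q(tail_quantile)].  Raises when essentially all of the
    latent-period mass lies below the burst onset D (the population would
    release no phage and the parameter set is invalid).
    """
    if dist.family == "point-mass":
        denom = float(burst_size_shape(dist.tau_0, r_beta, D, beta_tau50))
    else:
        hi = float(dist.ppf(tail_quantile))
        lo = float(dist.tau_min)

        def integrand(t):
            return burst_size_shape(t, r_beta, D, beta_tau50) * dist.pdf(t)

        points = sorted({p for p in (D, beta_tau50) if lo < p < hi})
        denom, _ = integrate.quad(
            integrand, lo, hi, points=points or None,
            epsrel=epsrel, epsabs=0.0, limit=500,
        )
    if denom < 1e-12:
        raise InvalidParameterSetError(
            "latent-period mass lies entirely below the burst onset D; "
            f"normalization integral = {denom:.3e}"
        )
    return beta_0_mean / denom
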