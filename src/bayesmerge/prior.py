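"""Fragment-length priors.

The latent variable of the merging model is the original molecule length
``i``. Two priors are supported:

* ``uniform`` — every candidate length, and the "longer than ``l1+l2``"
  hypothesis, receives the same mass ``1/(l1+l2+2)``. Used when nothing is
  known about the library's insert-size distribution.
* ``lognormal`` — the density ``1/(i·sigma·sqrt(2*pi)) · exp(-(ln i - mu)^2 /
  (2 sigma^2))``, the family that best describes sequencing-library insert
  sizes (ancient-DNA libraries have small mu and sigma; modern libraries sit
  far to the right). The no-merge hypothesis receives the tail mass
  ``1 - cdf(l1+l2)``.

Fitting from observed lengths uses the closed-form maximum-likelihood
estimator: ``mu = mean(ln x)``, ``sigma = sqrt(mean((ln x - mu)^2))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class LengthPrior:
    """Prior over the original molecule length.

    Parameters
    ----------
    kind : {"uniform", "lognormal"}
    mu, sigma : float
        Location and scale on the log-length scale (lognormal only);
        ``sigma`` must be positive.
    """

    kind: str = "uniform"
    mu: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "lognormal"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "lognormal" and not self.sigma > 0:
            raise ValueError("sigma must be > 0 for a lognormal prior")

    # -- per-length log mass -------------------------------------------------
    def log_prior(self, i: int, n_hypotheses: int) -> float:
        """Log prior mass for candidate length ``i``.

        ``n_hypotheses`` is the total hypothesis count (all lengths plus
        no-merge) used to spread the uniform prior. For the lognormal prior
        ``i = 0`` (adaptor dimer) is evaluated at 0.5 as a continuity
        correction, the density being undefined at zero.
        """
        if i < 0:
            raise ValueError("length must be >= 0")
        if self.kind == "uniform":
            return -math.log(n_hypotheses)
        x = 0.5 if i == 0 else float(i)
        return lognormal_logpdf(x, self.mu, self.sigma)

    def log_tail(self, L: int, n_hypotheses: int) -> float:
        """Log prior mass of molecule length exceeding ``L``."""
        if self.kind == "uniform":
            return -math.log(n_hypotheses)
        return math.log(tail_mass(L, self))


def lognormal_logpdf(i: float, mu: float, sigma: float) -> float:
    """Log density of the log-normal distribution at length ``i``."""
    if i <= 0:
        raise ValueError("length must be > 0 for the log-normal density")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return stats.lognorm.logpdf(i, s=sigma, scale=math.exp(mu))


def tail_mass(L: float, prior: LengthPrior) -> float:
    """Survival mass ``1 - cdf(L)`` of the prior.

    For a uniform prior this is not defined by a density; the caller spreads
    per-hypothesis mass instead, and this function returns 1.0 so a uniform
    prior never changes a likelihood through its tail.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    if prior.kind == "uniform":
        return 1.0
    return float(stats.lognorm.sf(L, s=prior.sigma, scale=math.exp(prior.mu)))


def fit_lognormal(lengths) -> tuple[float, float]:
    """Closed-form MLE of (mu, sigma) from observed molecule lengths.

    Uses the 1/n (maximum-likelihood) variance. Raises on non-positive
    lengths, on fewer than two observations, and on a degenerate fit
    (all lengths identical, sigma = 0).
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 lengths to fit")
    if np.any(x <= 0):
        raise ValueError("all lengths must be positive")
    logx = np.log(x)
    mu = float(logx.mean())
    sigma = float(np.sqrt(np.mean((logx - mu) ** 2)))
    if sigma == 0.0:
        raise ValueError("degenerate fit: all lengths identical (sigma = 0)")
    return mu, sigma


def fit_from_file(path) -> tuple[float, float]:
    """Fit the log-normal prior from a one-length-per-line text file."""
    lengths = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                lengths.append(int(line))
    return fit_lognormal(lengths)
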