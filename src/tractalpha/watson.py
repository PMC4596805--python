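"""Bipolar Watson distribution on the unit sphere.

The Watson distribution is the fundamental antipodally-symmetric
distribution for axial data: density proportional to exp(kappa (mu.n)^2)
around a mean axis +/-mu, with concentration kappa >= 0 (the bipolar
regime).  The normalizer is the Kummer confluent hypergeometric function
M(1/2, 3/2, kappa); with the uniform surface measure included the density
is

    p(+/-n; mu, kappa) = exp(kappa (mu.n)^2) / (4 pi M(1/2, 3/2, kappa)),

which integrates to 1 over the sphere.  The maximum likelihood estimate of
the mean axis of a sample is the first eigenvector of its scatter matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError
from .geometry import scatter_summary

logger = logging.getLogger(__name__)


@dataclass
class WatsonParams:
    """Mean axis ``mu`` (unit vector) and concentration ``kappa`` >= 0."""

    mu: np.ndarray
    kappa: float

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        if abs(np.linalg.norm(self.mu) - 1.0) > 1e-6:
            raise ConfigurationError("Watson mean axis mu must be a unit vector")
        if self.kappa < 0:
            raise ConfigurationError(
                "only the bipolar regime kappa >= 0 is supported"
            )


def kummer_m(kappa: float) -> float:
    """Kummer function M(1/2, 3/2, kappa) by its power series.

    Sums sum_k [(1/2)_k / (3/2)_k] kappa^k / k! = sum_k kappa^k / ((2k+1) k!)
    to relative tolerance 1e-12.  Well behaved for all kappa >= 0.
    """
    if kappa < 0:
        raise ConfigurationError("kummer_m requires kappa >= 0 (bipolar regime)")
    total = term = 1.0
    k = 0
    while True:
        k += 1
        # ratio of consecutive terms: (1/2+k-1)/(3/2+k-1) * kappa/k
        term *= (2 * k - 1) / (2 * k + 1) * kappa / k
        total += term
        if term < 1e-12 * total:
            return total


def watson_log_density(n, params: WatsonParams) -> float:
    """Log density at a unit axis ``n``, uniform surface measure on S^2."""
    n = np.asarray(n, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise DomainError("watson_log_density requires a unit axis")
    dot = float(params.mu @ n)
    return (params.kappa * dot * dot
            - np.log(kummer_m(params.kappa))
            - np.log(4.0 * np.pi))


def _uniform_axes(rng: np.random.Generator, count: int) -> np.ndarray:
    """Uniform unit vectors via the standard Gaussian normalization."""
    v = rng.standard_normal((count, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_watson(params: WatsonParams, count: int, seed) -> np.ndarray:
    """Draw ``count`` axes by rejection from a uniform-sphere proposal.

    The envelope is exp(kappa): a proposal n is accepted with probability
    exp(kappa ((mu.n)^2 - 1)).  Deterministic given ``seed``; the achieved
    acceptance rate is logged.
    """
    if count < 1:
        raise ConfigurationError("sample count must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty((count, 3))
    filled = 0
    proposed = 0
    while filled < count:
        batch = max(count - filled, 256)
        n = _uniform_axes(rng, batch)
        proposed += batch
        accept_p = np.exp(params.kappa * ((n @ params.mu) ** 2 - 1.0))
        keep = n[rng.random(batch) < accept_p]
        take = min(len(keep), count - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    logger.debug("Watson rejection sampling acceptance rate %.3f",
                 count / proposed)
    return out


def estimate_mean_axis(axes) -> np.ndarray:
    """ML mean axis of an axial sample: first scatter-matrix eigenvector."""
    return scatter_summary(axes).s1
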