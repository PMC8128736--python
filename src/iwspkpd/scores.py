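"""Probability model for integer withdrawal scores (0-10).

Severity ``lambda`` maps to a probability mass over the 11 possible scores
through a *truncated generalized Poisson* distribution with dispersion
coefficient ``delta``::

    p(y) \\propto lambda * (lambda + delta*y)**(y-1) * exp(-lambda - delta*y) / y!

renormalized over y = 0..10 (``delta = 0`` recovers the truncated ordinary
Poisson).  Serial correlation between consecutive scores is captured by a
Markov probability inflation: extra point mass is placed on the previous
score (pi0|0 if it was zero, pi0|x otherwise) and on scores within +/-1 and
+/-2 of it; the base distribution is scaled by one minus the total retained
inflation mass.  Targets outside 0..10 are dropped, shrinking that mass.

Scores above 3 indicate withdrawal severe enough to require intervention,
so ``risk_above_threshold`` (strictly greater than) is the clinical risk
read-out used by the weaning simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "N_SCORES",
    "SCORES",
    "MarkovInflation",
    "gp_truncated_pmf",
    "gp_truncated_pmf_matrix",
    "markov_inflate",
    "score_distribution",
    "expected_score",
    "sample_score",
    "risk_above_threshold",
    "validate_pmf",
]

N_SCORES = 11
SCORES = np.arange(N_SCORES)
_LOG_FACT = gammaln(SCORES + 1.0)


def validate_pmf(dist: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Check that ``dist`` is a pmf over scores 0..10 and return it as array."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (N_SCORES,):
        raise ValueError(f"distribution must have shape ({N_SCORES},)")
    if np.any(dist < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(dist.sum() - 1.0) > tol:
        raise ValueError("probabilities must sum to 1")
    return dist


def gp_truncated_pmf_matrix(lam: np.ndarray, delta: float) -> np.ndarray:
    """Vectorized truncated generalized Poisson pmf.

    Parameters
    ----------
    lam:
        Severity values, shape (n,); all must be > 0.
    delta:
        Dispersion coefficient in [0, 1).

    Returns
    -------
    (n, 11) array of probabilities, each row summing to 1.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if np.any(lam <= 0):
        raise ValueError("lambda must be > 0")
    if not 0 <= delta < 1:
        raise ValueError("delta must lie in [0, 1)")
    lamc = lam[:, None]
    shifted = lamc + delta * SCORES  # > 0 for delta >= 0
    # y = 0 column reduces to exp(-lambda) because (y-1)*log(lambda) cancels
    logu = (
        np.log(lamc)
        + (SCORES - 1) * np.log(shifted)
        - lamc
        - delta * SCORES
        - _LOG_FACT
    )
    logu -= logsumexp(logu, axis=1, keepdims=True)
    return np.exp(logu)


def gp_truncated_pmf(lam: float, delta: float) -> np.ndarray:
    """Truncated generalized Poisson pmf over scores 0..10 for scalar ``lam``."""
    return gp_truncated_pmf_matrix(np.array([float(lam)]), delta)[0]


@dataclass(frozen=True)
class MarkovInflation:
    """Probability-inflation parameters for serial score correlation.

    ``pi_same_prev0`` applies to repeating a previous score of zero,
    ``pi_same_prevx`` to repeating any nonzero previous score, and
    ``pi_pm1`` / ``pi_pm2`` to scores one / two points away.  The reference
    model constrains ``pi_pm1 == pi_pm2``.
    """

    pi_same_prev0: float
    pi_same_prevx: float
    pi_pm1: float
    pi_pm2: float

    def __post_init__(self) -> None:
        for name in ("pi_same_prev0", "pi_same_prevx", "pi_pm1", "pi_pm2"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")

    def point_masses(self, prev_score: int) -> np.ndarray:
        """Added point mass per score for a given previous score."""
        if not 0 <= prev_score <= 10:
            raise ValueError("prev_score must lie in 0..10")
        add = np.zeros(N_SCORES)
        add[prev_score] = self.pi_same_prev0 if prev_score == 0 else self.pi_same_prevx
        for off, pi in ((1, self.pi_pm1), (2, self.pi_pm2)):
            for tgt in (prev_score - off, prev_score + off):
                if 0 <= tgt <= 10:
                    add[tgt] += pi
        return add


def markov_inflate(
    base: np.ndarray, prev_score: int, infl: MarkovInflation
) -> np.ndarray:
    """Mix a base score distribution with Markov point-mass inflation.

    Returns ``(1 - Pi) * base + point masses`` where ``Pi`` is the total
    retained inflation mass (targets outside 0..10 are dropped first).
    """
    base = validate_pmf(base)
    add = infl.point_masses(int(prev_score))
    Pi = add.sum()
    if Pi >= 1:
        raise ValueError(f"total inflation mass {Pi:.4f} >= 1 is invalid")
    return (1.0 - Pi) * base + add


def score_distribution(
    lam: float,
    delta: float,
    infl: MarkovInflation | None = None,
    prev_score: int | None = None,
) -> np.ndarray:
    """Full conditional score distribution at severity ``lam``.

    The first observation of an individual has no previous score and uses
    the uninflated truncated generalized Poisson distribution.
    """
    base = gp_truncated_pmf(lam, delta)
    if infl is None or prev_score is None:
        return base
    return markov_inflate(base, prev_score, infl)


def expected_score(dist: np.ndarray) -> float:
    """Probability-weighted mean score, in [0, 10]."""
    return float(validate_pmf(dist) @ SCORES)


def sample_score(dist: np.ndarray, rng: np.random.Generator) -> int:
    """Inverse-CDF draw of an integer score from ``dist``."""
    dist = validate_pmf(dist)
    cdf = np.cumsum(dist)
    return int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))


def risk_above_threshold(dist: np.ndarray, threshold: int = 3) -> float:
    """Probability of a score *strictly above* ``threshold``.

    With the default threshold this is P(score > 3), the probability of
    withdrawal requiring intervention.
    """
    dist = validate_pmf(dist)
    return float(dist[threshold + 1 :].sum())
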