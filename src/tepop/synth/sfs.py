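"""Carrier-count (site frequency) model for simulated TE sites.

Each segregating TE site is carried by ``k`` of ``n`` strains with
``k = 1 + BetaBinomial(n - 1, sfs_skew, beta)`` — a shifted Beta-binomial
supported on {1, ..., n}.  Smaller ``sfs_skew`` (the Beta alpha) pushes
mass toward k = 1, producing the singleton-heavy spectra observed for
TE insertions in wild populations.  The singleton fraction has a closed
form (the pmf at k = 1), so the generator can be calibrated to any
target singleton fraction.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

DEFAULT_BETA = 3.0


def carrier_distribution(n_strains: int, sfs_skew: float, beta: float = DEFAULT_BETA):
    """Frozen distribution of ``k - 1`` (support {0, ..., n_strains - 1})."""
    if sfs_skew <= 0:
        raise ValueError("sfs_skew must be > 0")
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    return stats.betabinom(n_strains - 1, sfs_skew, beta)


def expected_singleton_fraction(n_strains: int, sfs_skew: float, beta: float = DEFAULT_BETA) -> float:
    """P(k = 1): the expected fraction of sites private to one strain."""
    return float(carrier_distribution(n_strains, sfs_skew, beta).pmf(0))


def solve_sfs_skew(
    n_strains: int, target_singleton_fraction: float, beta: float = DEFAULT_BETA
) -> float:
    """Invert the singleton fraction for the Beta alpha (``sfs_skew``).

    The singleton probability is strictly decreasing in alpha, so a
    bracketed root always exists for attainable targets.
    """
    if not 0 < target_singleton_fraction < 1:
        raise ValueError("target singleton fraction must be in (0, 1)")

    def gap(log_alpha: float) -> float:
        return expected_singleton_fraction(n_strains, np.exp(log_alpha), beta) - target_singleton_fraction

    lo, hi = np.log(1e-6), np.log(1e4)
    if gap(lo) < 0 or gap(hi) > 0:
        raise ValueError("target singleton fraction not attainable for this n/beta")
    return float(np.exp(optimize.brentq(gap, lo, hi, xtol=1e-12)))


def draw_carrier_counts(
    n_sites: int,
    n_strains: int,
    sfs_skew: float,
    rng: np.random.Generator,
    beta: float = DEFAULT_BETA,
    max_carriers: int | None = None,
) -> np.ndarray:
    """Draw per-site carrier counts; optionally redraw counts above a cap.

    ``max_carriers = n_strains - 1`` is used for reference-site excisions,
    which by definition leave the reference allele in at least one strain.
    """
    dist = carrier_distribution(n_strains, sfs_skew, beta)
    k = 1 + dist.rvs(size=n_sites, random_state=rng)
    if max_carriers is not None:
        for _ in range(1000):
            over = k > max_carriers
            if not over.any():
                break
            k[over] = 1 + dist.rvs(size=int(over.sum()), random_state=rng)
        k = np.minimum(k, max_carriers)
    return k.astype(int)
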