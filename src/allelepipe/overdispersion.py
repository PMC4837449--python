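"""Beta-binomial null model for allelic ratios and overdispersion estimation.

Under the null of no allelic imbalance the reference-read count K at a site
with n informative reads is beta-binomial with mean 1/2 and overdispersion
rho = 1/(a+b+1), where the beta shapes satisfy a = b = (1-rho)/(2 rho);
rho = 0 is the plain binomial limit.  rho is estimated per data set by
matching the expected allelic-ratio histogram to the empirical one (sites
with n >= 6 reads) under least sum of squared errors (LSSE): a coarse grid
over rho in {0, 0.1, ..., 1} followed by a bisection refinement of the
bracketing interval.

Data sets whose estimated rho is extreme are flagged for removal before
pooling: allelic-ratio spread that wide usually signals uneven or sparse
coverage rather than biology (default thresholds 0.125 for RNA-seq,
0.3 for ChIP-seq).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import betaln, gammaln

from .mapping import AllelicCount

__all__ = [
    "BetaBinomialNull",
    "RatioHistogram",
    "RhoEstimate",
    "beta_binomial_pmf",
    "pmf_vector",
    "cap_counts",
    "expected_histogram",
    "empirical_histogram",
    "estimate_rho",
    "flag_overdispersed",
    "MIN_READS",
    "N_CAP",
    "DEFAULT_BINS",
    "RHO_FLAG_THRESHOLDS",
]

MIN_READS = 6  # histogram and testing floor on informative reads
N_CAP = 1000  # counts above this are rescaled, preserving the allelic ratio
DEFAULT_BINS = 51
RHO_FLAG_THRESHOLDS = {"rna": 0.125, "chip": 0.3}


@dataclass(frozen=True)
class BetaBinomialNull:
    """The null model: symmetric beta-binomial with mean fixed at 1/2."""

    rho: float
    mu: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")

    @property
    def a(self) -> float:
        if self.rho == 0.0:
            return float("inf")
        return (1.0 - self.rho) / (2.0 * self.rho)

    b = a  # symmetry from mu = 0.5


def cap_counts(k: int, n: int, cap: int = N_CAP) -> tuple[int, int]:
    """Rescale (k, n) to n = cap when n exceeds it, preserving the ratio."""
    if n <= cap:
        return k, n
    return int(round(k / n * cap)), cap


@lru_cache(maxsize=4096)
def _pmf_vector_cached(n: int, rho: float) -> np.ndarray:
    k = np.arange(n + 1)
    if rho == 0.0:
        logp = (
            gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1) - n * np.log(2.0)
        )
        return np.exp(logp)
    if rho == 1.0:
        # degenerate beta limit: all mass at the extremes
        p = np.zeros(n + 1)
        p[0] = p[n] = 0.5
        return p
    a = (1.0 - rho) / (2.0 * rho)
    logp = (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + betaln(k + a, n - k + a)
        - betaln(a, a)
    )
    return np.exp(logp)


def pmf_vector(n: int, rho: float) -> np.ndarray:
    """P(K = k) for k = 0..n under the symmetric beta-binomial null.

    Accepts rho in [0, 1]; rho = 1 is the two-point extreme-mass limit,
    used only when evaluating the LSSE grid endpoint.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    return _pmf_vector_cached(int(n), float(rho))


def beta_binomial_pmf(k: int, n: int, rho: float) -> float:
    """P(K = k) = C(n,k) B(k+a, n-k+a) / B(a,a) with a = (1-rho)/(2 rho)."""
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    k, n = cap_counts(k, n)
    return float(pmf_vector(n, rho)[k])


@dataclass
class RatioHistogram:
    """Normalized allelic-ratio histogram plus the contributing n multiset."""

    bin_edges: np.ndarray
    mass: np.ndarray
    n_values: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        total = self.mass.sum()
        if total > 0:
            self.mass = self.mass / total


def _bin_of(ratios: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, ratios, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def default_bin_edges(n_bins: int = DEFAULT_BINS) -> np.ndarray:
    return np.linspace(0.0, 1.0, n_bins + 1)


def empirical_histogram(
    counts: list[AllelicCount],
    bin_edges: np.ndarray | None = None,
    min_reads: int = MIN_READS,
) -> RatioHistogram:
    """Equal-weight histogram of observed allelic ratios (sites with n >= 6)."""
    edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges)
    eligible = [c for c in counts if c.n >= min_reads]
    if not eligible:
        raise ValueError(f"no SNVs with n >= {min_reads}")
    n_values: dict[int, int] = {}
    ratios = np.empty(len(eligible))
    for i, c in enumerate(eligible):
        k, n = cap_counts(c.n_ref, c.n)
        ratios[i] = k / n
        n_values[n] = n_values.get(n, 0) + 1
    mass = np.zeros(len(edges) - 1)
    np.add.at(mass, _bin_of(ratios, edges), 1.0)
    return RatioHistogram(bin_edges=edges, mass=mass, n_values=n_values)


def expected_histogram(
    rho: float,
    n_values: dict[int, int],
    bin_edges: np.ndarray | None = None,
) -> RatioHistogram:
    """Null allelic-ratio histogram implied by rho over the observed n's.

    For each n, the beta-binomial mass at k is placed in the bin containing
    k/n; distinct n's are averaged with their multiset weights.
    """
    if not n_values:
        raise ValueError("empty n multiset")
    edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges)
    mass = np.zeros(len(edges) - 1)
    for n, weight in n_values.items():
        pmf = pmf_vector(n, rho)
        ratios = np.arange(n + 1) / n
        np.add.at(mass, _bin_of(ratios, edges), pmf * weight)
    return RatioHistogram(bin_edges=edges, mass=mass, n_values=dict(n_values))


@dataclass(frozen=True)
class RhoEstimate:
    rho: float
    lsse: float
    iterations: int


def _lsse(empirical: RatioHistogram, rho: float) -> float:
    exp = expected_histogram(rho, empirical.n_values, empirical.bin_edges)
    return float(np.sum((empirical.mass - exp.mass) ** 2))


def estimate_rho(
    counts: list[AllelicCount],
    bin_edges: np.ndarray | None = None,
    grid_step: float = 0.1,
    tol: float = 1e-4,
    max_iter: int = 30,
) -> RhoEstimate:
    """LSSE fit of rho: coarse grid over [0, 1] then bisection refinement.

    The grid minimum is bracketed by its neighbours and the bracket is
    shrunk by comparing LSSE at the two interior midpoints until narrower
    than ``tol``.  The estimator involves no randomness.
    """
    emp = empirical_histogram(counts, bin_edges)
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    losses = [_lsse(emp, r) for r in grid]
    i = int(np.argmin(losses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    best_rho, best_loss = float(grid[i]), losses[i]
    iterations = 0
    while hi - lo > tol and iterations < max_iter:
        m1 = lo + (hi - lo) / 3.0
        m2 = hi - (hi - lo) / 3.0
        f1, f2 = _lsse(emp, m1), _lsse(emp, m2)
        if f1 < best_loss:
            best_rho, best_loss = m1, f1
        if f2 < best_loss:
            best_rho, best_loss = m2, f2
        if f1 <= f2:
            hi = m2
        else:
            lo = m1
        iterations += 1
    return RhoEstimate(rho=best_rho, lsse=best_loss, iterations=iterations)


def flag_overdispersed(
    rho: float,
    assay: str,
    thresholds: dict[str, float] = RHO_FLAG_THRESHOLDS,
) -> bool:
    """True when the data set should be dropped before pooling (rho >= threshold)."""
    if assay not in thresholds:
        raise ValueError(f"unknown assay {assay!r}; expected one of {set(thresholds)}")
    return rho >= thresholds[assay]
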