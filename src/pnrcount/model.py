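"""Convolution-binomial measurement model for photon-number-resolved counting.

A sample contains ``m`` fluorophore species; species ``j`` has ``M_j``
emitters, each yielding a detected photon in a single excitation pulse with
probability ``p_j``.  The detected photon number per pulse is then the sum of
``m`` independent binomial draws, so its probability mass function is the
discrete convolution of the per-species binomial PMFs.  Repeating the pulse
``nu`` times produces a count histogram ``[C_0, ..., C_N]`` — the only data
the estimators in this package ever see.

This module holds the parameter and data containers, the PMF (both a fast
convolution path and a brute-force partition-sum oracle), the log-likelihood
of a histogram, and the closed-form moments of the model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln


__all__ = [
    "SpeciesParams",
    "MixtureParams",
    "PhotonHistogram",
    "PartitionSet",
    "binomial_pmf",
    "enumerate_partitions",
    "mixture_pmf",
    "mixture_pmf_bruteforce",
    "log_likelihood",
    "theoretical_moments",
    "expected_histogram",
]


@dataclass(frozen=True)
class SpeciesParams:
    """One emitter species: ``M`` emitters with per-emitter detection probability ``p``."""

    M: int
    p: float

    def __post_init__(self) -> None:
        if int(self.M) != self.M or self.M < 1:
            raise ValueError(f"emitter count M must be a positive integer, got {self.M}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"detection probability p must lie in (0, 1], got {self.p}")
        object.__setattr__(self, "M", int(self.M))
        object.__setattr__(self, "p", float(self.p))


@dataclass(frozen=True)
class MixtureParams:
    """Ordered collection of species; the full parameter vector [M_1,p_1,...,M_m,p_m]."""

    species: tuple[SpeciesParams, ...]

    def __post_init__(self) -> None:
        species = tuple(
            s if isinstance(s, SpeciesParams) else SpeciesParams(*s) for s in self.species
        )
        if len(species) < 1:
            raise ValueError("a mixture needs at least one species")
        object.__setattr__(self, "species", species)

    @classmethod
    def from_flat(cls, flat: Sequence[float]) -> "MixtureParams":
        """Build from the flat layout [M_1, p_1, ..., M_m, p_m]."""
        if len(flat) == 0 or len(flat) % 2 != 0:
            raise ValueError("flat parameter vector must have even, positive length")
        pairs = [(flat[i], flat[i + 1]) for i in range(0, len(flat), 2)]
        return cls(tuple(SpeciesParams(int(M), p) for M, p in pairs))

    def to_flat(self) -> list[float]:
        out: list[float] = []
        for s in self.species:
            out.extend([s.M, s.p])
        return out

    @property
    def m(self) -> int:
        return len(self.species)

    @property
    def M_total(self) -> int:
        return sum(s.M for s in self.species)

    @property
    def Ms(self) -> np.ndarray:
        return np.array([s.M for s in self.species], dtype=np.int64)

    @property
    def ps(self) -> np.ndarray:
        return np.array([s.p for s in self.species], dtype=float)

    def canonical(self) -> "MixtureParams":
        """Reorder species by ascending p, ties broken by ascending M.

        The likelihood is invariant under species permutation (label
        switching), so a fixed convention is needed for reporting and for
        matching estimates against ground truth.
        """
        order = sorted(range(self.m), key=lambda j: (self.species[j].p, self.species[j].M))
        return MixtureParams(tuple(self.species[j] for j in order))


@dataclass(frozen=True)
class PhotonHistogram:
    """Occurrences ``C_i`` of each detected photon number over ``nu`` experiments.

    ``counts[i]`` is the number of pulses in which exactly ``i`` photons were
    detected.  Counts are usually integers; fractional values are admitted so
    that the expected (infinite-data) histogram ``nu * pmf`` can be pushed
    through the same estimator code paths.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(c < 0):
            raise ValueError("histogram counts must be non-negative")
        if c.sum() <= 0:
            raise ValueError("histogram must contain at least one experiment (nu >= 1)")
        # trim trailing empty bins so N is the largest observed photon number
        last = int(np.nonzero(c)[0][-1])
        object.__setattr__(self, "counts", c[: last + 1].copy())

    @property
    def nu(self) -> float:
        """Total number of experiments, sum of all counts."""
        return float(self.counts.sum())

    @property
    def N(self) -> int:
        """Largest photon number observed with non-zero count."""
        return len(self.counts) - 1

    @classmethod
    def from_samples(cls, photons: Iterable[int]) -> "PhotonHistogram":
        arr = np.asarray(list(photons), dtype=np.int64)
        return cls(np.bincount(arr).astype(float))


@dataclass(frozen=True)
class PartitionSet:
    """All ways to split a total ``y`` into per-species parts bounded by ``caps``."""

    total: int
    caps: tuple[int, ...]
    tuples: frozenset = field(default_factory=frozenset)


def binomial_pmf(M: int, p: float) -> np.ndarray:
    """PMF of a Binomial(M, p) draw, entries y = 0..M.

    Entry y equals C(M, y) p^y (1-p)^(M-y).  p = 0 and p = 1 are admitted as
    degenerate point masses.  Evaluated in log space so extreme p stay exact
    to double precision.
    """
    if int(M) != M or M < 1:
        raise ValueError(f"M must be a positive integer, got {M}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    M = int(M)
    y = np.arange(M + 1)
    if p == 0.0 or p == 1.0:
        pmf = np.zeros(M + 1)
        pmf[-1 if p == 1.0 else 0] = 1.0
        return pmf
    lchoose = gammaln(M + 1) - gammaln(y + 1) - gammaln(M - y + 1)
    return np.exp(lchoose + y * np.log(p) + (M - y) * np.log1p(-p))


def enumerate_partitions(y: int, caps: Sequence[int]) -> PartitionSet:
    """Enumerate all capped compositions of ``y`` into ``len(caps)`` parts.

    Returns the exhaustive, duplicate-free set of tuples ``(y_1, ..., y_m)``
    with ``sum(y_j) == y`` and ``0 <= y_j <= caps[j]``; empty when
    ``y > sum(caps)``.
    """
    if y < 0:
        raise ValueError("total y must be non-negative")
    caps = tuple(int(c) for c in caps)
    if any(c < 0 for c in caps):
        raise ValueError("caps must be non-negative")

    def _rec(remaining: int, idx: int, prefix: tuple[int, ...]):
        if idx == len(caps) - 1:
            if 0 <= remaining <= caps[idx]:
                yield prefix + (remaining,)
            return
        # bound y_idx so the rest can still absorb the remainder
        tail_cap = sum(caps[idx + 1 :])
        lo = max(0, remaining - tail_cap)
        hi = min(caps[idx], remaining)
        for v in range(lo, hi + 1):
            yield from _rec(remaining - v, idx + 1, prefix + (v,))

    tuples = frozenset(_rec(y, 0, ())) if caps else frozenset({()} if y == 0 else set())
    return PartitionSet(total=y, caps=caps, tuples=tuples)


def mixture_pmf(theta: MixtureParams) -> np.ndarray:
    """PMF of the summed photon number, by sequential discrete convolution.

    Length is ``M_total + 1``; invariant under permutation of species.
    """
    pmf = binomial_pmf(theta.species[0].M, theta.species[0].p)
    for s in theta.species[1:]:
        pmf = np.convolve(pmf, binomial_pmf(s.M, s.p))
    return pmf


def mixture_pmf_bruteforce(theta: MixtureParams) -> np.ndarray:
    """Reference PMF via explicit partition sums (oracle for :func:`mixture_pmf`).

    pr(Y = y) = sum over all capped compositions of y of the product of the
    per-species binomial probabilities.  Exponential in m — testing use only.
    """
    per_species = [binomial_pmf(s.M, s.p) for s in theta.species]
    caps = [s.M for s in theta.species]
    out = np.zeros(theta.M_total + 1)
    for y in range(theta.M_total + 1):
        total = 0.0
        for parts in enumerate_partitions(y, caps).tuples:
            prod = 1.0
            for j, yj in enumerate(parts):
                prod *= per_species[j][yj]
            total += prod
        out[y] = total
    return out


def log_likelihood(hist: PhotonHistogram, theta: MixtureParams) -> float:
    """Log-likelihood sum_i C_i log pr(Y = i | theta) of a count histogram.

    Returns ``-inf`` when any observed bin lies outside the model support or
    has zero model probability.  Computed in log space from the convolved PMF
    to stay finite at large total emitter numbers.
    """
    if hist.nu <= 0:
        raise ValueError("histogram has no experiments")
    if hist.N > theta.M_total:
        return float("-inf")
    pmf = mixture_pmf(theta)[: hist.N + 1]
    obs = hist.counts > 0
    if np.any(pmf[obs] <= 0.0):
        return float("-inf")
    with np.errstate(divide="ignore"):
        logpmf = np.where(obs, np.log(np.where(pmf > 0, pmf, 1.0)), 0.0)
    return float(np.dot(hist.counts, logpmf))


def theoretical_moments(theta: MixtureParams) -> tuple[float, float, float, float]:
    """Mean and central moments 2-4 of the summed photon number.

    The mean and the 2nd/3rd central moments are additive over independent
    species (they are cumulants):

    mu1 = sum M_j p_j
    mu2 = sum M_j p_j (1 - p_j)
    mu3 = sum (1 - p_j)(1 - 2 p_j) M_j p_j

    The 4th central moment is not additive; it is assembled from the
    additive 4th cumulants plus the cross term:

    mu4 = sum M_j p_j (1 - p_j)(1 - 6 p_j (1 - p_j))  +  3 mu2^2
    """
    M, p = theta.Ms.astype(float), theta.ps
    q = 1.0 - p
    mu1 = float(np.sum(M * p))
    mu2 = float(np.sum(M * p * q))
    mu3 = float(np.sum(q * (1.0 - 2.0 * p) * M * p))
    kappa4 = float(np.sum(M * p * q * (1.0 - 6.0 * p * q)))
    mu4 = kappa4 + 3.0 * mu2**2
    return mu1, mu2, mu3, mu4


def expected_histogram(theta: MixtureParams, nu: float) -> PhotonHistogram:
    """The infinite-data limit histogram: fractional counts ``nu * pmf``."""
    return PhotonHistogram(nu * mixture_pmf(theta))
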