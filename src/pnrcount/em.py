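"""Expectation-maximization for the convolution-binomial mixture.

The complete data of one pulse are the per-species photon numbers
``(y_1, ..., y_m)``; only their sum ``i`` is observed.  The E-step therefore
weights every capped composition of each observed total by its conditional
probability under the current parameters; the M-step then has a closed-form
update for each detection probability,

    p_j  <-  (sum_i C_i E[y_j | Y=i]) / (M_j nu),

and an exhaustive integer scan for each emitter count.  The expected
per-species counts are computed through leave-one-species-out convolutions
rather than explicit partition enumeration (the two agree; enumeration is
kept as a test oracle), which keeps an iteration polynomial in ``m``.

Each iteration can only increase the log-likelihood, so convergence is
monitored on both the parameter change and the log-likelihood change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .model import (
    MixtureParams,
    PhotonHistogram,
    SpeciesParams,
    binomial_pmf,
    enumerate_partitions,
    log_likelihood,
)

__all__ = [
    "EMSettings",
    "FitResult",
    "e_step_weights",
    "posterior_marginals",
    "expected_species_counts",
    "update_p",
    "update_M",
    "run_em",
]

_P_CLAMP = 1e-12


@dataclass(frozen=True)
class EMSettings:
    """Convergence controls for the EM iteration.

    tol_p:    stop when max_j |p_j^(s+1) - p_j^(s)| falls below this (and no
              emitter count changed).
    tol_ll:   stop when the log-likelihood improvement falls below this.
    max_iter: hard iteration cap; exceeding it reports converged=False.
    M_max:    largest emitter count admitted in the integer scan.
    fix_M:    when True only the detection probabilities are updated
              (the inner loop of the combination search).
    """

    tol_p: float = 1e-9
    tol_ll: float = 1e-10
    max_iter: int = 10_000
    M_max: int = 30
    fix_M: bool = False

    def __post_init__(self) -> None:
        if self.tol_p <= 0 or self.tol_ll <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class FitResult:
    theta_hat: MixtureParams
    loglik: float
    converged: bool
    iterations: int
    seed_provenance: str = ""
    trace: tuple[float, ...] = field(default_factory=tuple, repr=False)


def e_step_weights(i: int, theta_s: MixtureParams) -> dict[tuple[int, ...], float]:
    """Conditional probability of each composition of total ``i`` (oracle path).

    w_y = f(y | theta) / L(i | theta) over the capped compositions of ``i``;
    the weights form a probability distribution.  Cost is the partition-set
    size — use :func:`posterior_marginals` in production code.
    """
    if i > theta_s.M_total:
        raise ValueError(f"photon number {i} exceeds model support {theta_s.M_total}")
    pmfs = [binomial_pmf(s.M, s.p) for s in theta_s.species]
    caps = [s.M for s in theta_s.species]
    raw = {}
    for parts in enumerate_partitions(i, caps).tuples:
        w = 1.0
        for j, yj in enumerate(parts):
            w *= pmfs[j][yj]
        raw[parts] = w
    total = sum(raw.values())
    if total <= 0:
        raise ValueError(f"observed photon number {i} has zero model probability")
    return {parts: w / total for parts, w in raw.items()}


def _conv_all(pmfs: list[np.ndarray]) -> np.ndarray:
    out = pmfs[0]
    for q in pmfs[1:]:
        out = np.convolve(out, q)
    return out


def posterior_marginals(N: int, theta_s: MixtureParams) -> list[np.ndarray]:
    """Per-species conditional distributions of y_j given each total i = 0..N.

    Returns one ``(N+1, M_j+1)`` matrix per species with
    ``W_j[i, y] = P(y_j = y | Y = i, theta_s)``, computed as
    ``pr_j(y) * rest_j(i - y) / L(i)`` where ``rest_j`` is the convolution of
    all other species' PMFs.
    """
    if N > theta_s.M_total:
        raise ValueError(f"photon number {N} exceeds model support {theta_s.M_total}")
    pmfs = [binomial_pmf(s.M, s.p) for s in theta_s.species]
    L = _conv_all(pmfs)[: N + 1]
    out: list[np.ndarray] = []
    for j, pj in enumerate(pmfs):
        rest = _conv_all([q for k, q in enumerate(pmfs) if k != j]) if len(pmfs) > 1 else None
        Mj = len(pj) - 1
        R = np.zeros((N + 1, Mj + 1))
        if rest is None:
            for y in range(min(Mj, N) + 1):
                R[y, y] = 1.0
        else:
            for y in range(Mj + 1):
                hi = min(N - y, len(rest) - 1)
                if hi >= 0:
                    R[y : y + hi + 1, y] = rest[: hi + 1]
        W = R * pj[None, :]
        rows = W.sum(axis=1)
        # rows match L; normalize where the total has support
        ok = rows > 0
        W[ok] /= rows[ok, None]
        out.append(W)
    return out


def expected_species_counts(hist: PhotonHistogram, theta_s: MixtureParams) -> np.ndarray:
    """E-step statistic sum_i C_i E[y_j | Y=i] for each species.

    The entries sum to the total number of detected photons, sum_i C_i i.
    """
    W = posterior_marginals(hist.N, theta_s)
    return np.array(
        [float(hist.counts @ (Wj @ np.arange(Wj.shape[1]))) for Wj in W]
    )


def update_p(hist: PhotonHistogram, theta_s: MixtureParams) -> np.ndarray:
    """Closed-form M-step update of the detection probabilities."""
    S = expected_species_counts(hist, theta_s)
    return S / (theta_s.Ms * hist.nu)


def _log_binom_pmf_matrix(M_values: np.ndarray, p: float, y_max: int) -> np.ndarray:
    """log Binomial(M, p) PMF on y = 0..y_max for every M in ``M_values``."""
    y = np.arange(y_max + 1)[None, :]
    M = M_values[:, None].astype(float)
    p = min(max(p, _P_CLAMP), 1.0 - _P_CLAMP)
    return (
        gammaln(M + 1)
        - gammaln(y + 1)
        - gammaln(M - y + 1)
        + y * np.log(p)
        + (M - y) * np.log1p(-p)
    )


def update_M(
    hist: PhotonHistogram,
    theta_s: MixtureParams,
    p_new: np.ndarray,
    M_max: int = 30,
) -> np.ndarray:
    """Integer M-step: exhaustive scan of each species' expected log-likelihood.

    For species j the objective is Q_j(M) = sum_y G_j[y] log Binom(M, p_j)[y]
    with G_j the expected count of pulses contributing y photons from species
    j under the current parameters.  Ties break toward the smaller M.
    """
    W = posterior_marginals(hist.N, theta_s)
    Ms = theta_s.Ms
    out = np.empty(theta_s.m, dtype=np.int64)
    for j, Wj in enumerate(W):
        G = hist.counts @ Wj  # expected occurrences of each y_j
        ymax = int(np.nonzero(G > 0)[0][-1]) if np.any(G > 0) else 0
        others = int(Ms.sum() - Ms[j])
        lo = max(1, ymax, hist.N - others)
        if lo > M_max:
            raise ValueError(
                f"no admissible emitter count for species {j}: need M >= {lo} > M_max={M_max}"
            )
        cand = np.arange(lo, M_max + 1)
        logpmf = _log_binom_pmf_matrix(cand, float(p_new[j]), ymax)
        Q = logpmf @ G[: ymax + 1]
        out[j] = int(cand[int(np.argmax(Q))])  # argmax returns first max: smaller M wins ties
    return out


def run_em(
    hist: PhotonHistogram,
    theta_init: MixtureParams,
    settings: EMSettings | None = None,
    seed_provenance: str = "user-supplied init",
) -> FitResult:
    """Iterate EM from ``theta_init`` until convergence or the iteration cap.

    The log-likelihood trace is non-decreasing (up to ~1e-9 numerical slack).
    Non-convergence is reported via ``converged=False``, never raised.
    """
    settings = settings or EMSettings()
    theta = theta_init
    ll = log_likelihood(hist, theta)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, settings.max_iter + 1):
        p_new = np.clip(update_p(hist, theta), _P_CLAMP, 1.0 - _P_CLAMP)
        if settings.fix_M:
            M_new = theta.Ms
        else:
            M_new = update_M(hist, theta, p_new, M_max=settings.M_max)
        theta_new = MixtureParams(
            tuple(SpeciesParams(int(M), float(p)) for M, p in zip(M_new, p_new))
        )
        ll_new = log_likelihood(hist, theta_new)
        dp = float(np.max(np.abs(p_new - theta.ps)))
        dM = int(np.max(np.abs(M_new - theta.Ms)))
        theta, prev_ll, ll = theta_new, ll, ll_new
        trace.append(ll)
        if (dM == 0 and dp < settings.tol_p) or abs(ll - prev_ll) < settings.tol_ll:
            converged = True
            break
    return FitResult(
        theta_hat=theta,
        loglik=ll,
        converged=converged,
        iterations=it,
        seed_provenance=seed_provenance,
        trace=tuple(trace),
    )
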