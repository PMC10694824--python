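"""Fisher information and Cramér–Rao lower bounds for the mixture model.

The emitter counts are integers, so the usual differentiation underlying the
Fisher information does not directly apply.  Following the standard device
for binomial-type models, the factorials in the binomial coefficient are
relaxed through the Gamma function, making the PMF a smooth function of a
real-valued ``M`` that coincides with the discrete PMF at integer arguments;
the score in ``M`` then involves digamma functions,

    d log pr / dM = psi(M+1) - psi(M-y+1) + log(1-p),

and the score in ``p`` is the familiar  y/p - (M-y)/(1-p).

Two information matrices are offered.  ``observed`` (default) is the
information carried by the summed photon number — the statistic the detector
actually records — and is the right reference for the Monte-Carlo RMSE
comparisons.  ``as_printed`` sums the score products of the joint
per-species outcome over all capped compositions, i.e. the complete-data
information; it upper-bounds the observed one in the Loewner order.

Parameter order throughout is ``[M_1, p_1, ..., M_m, p_m]``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

from .model import MixtureParams

__all__ = [
    "FisherResult",
    "relaxed_pmf",
    "dpmf_dM",
    "dpmf_dp",
    "fisher_information",
    "crlb_at",
    "required_nu",
]

# Reciprocal condition below machine epsilon means the information matrix is
# numerically rank-deficient (duplicated species make it exactly singular);
# legitimately ill-conditioned three-species FIMs sit just above this.
_RCOND_SINGULAR = float(np.finfo(float).eps)


@dataclass(frozen=True)
class FisherResult:
    matrix: np.ndarray
    singular: bool
    crlb: np.ndarray | None = None
    nu: float = 1.0


def relaxed_pmf(M: float, y: int, p: float) -> float:
    """Binomial PMF with the binomial coefficient continued to real ``M``.

    Coincides with the discrete PMF at integer ``M``; requires ``M >= y``
    and ``0 < p < 1``.
    """
    if M < y or y < 0:
        raise ValueError(f"need M >= y >= 0, got M={M}, y={y}")
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie strictly in (0, 1), got {p}")
    return float(
        np.exp(
            gammaln(M + 1)
            - gammaln(M - y + 1)
            - gammaln(y + 1)
            + y * np.log(p)
            + (M - y) * np.log1p(-p)
        )
    )


def dpmf_dM(M: float, y: int, p: float) -> float:
    """Derivative of the relaxed PMF in the (real) emitter count."""
    return relaxed_pmf(M, y, p) * (digamma(M + 1) - digamma(M - y + 1) + np.log1p(-p))


def dpmf_dp(M: float, y: int, p: float) -> float:
    """Derivative of the binomial PMF in the detection probability."""
    return relaxed_pmf(M, y, p) * (y / p - (M - y) / (1.0 - p))


def _species_score_vectors(theta: MixtureParams):
    """Per-species PMF and its two score-component vectors over y = 0..M_j."""
    pr, dM, dp = [], [], []
    for s in theta.species:
        ys = np.arange(s.M + 1)
        pj = np.array([relaxed_pmf(s.M, int(y), s.p) for y in ys])
        dMj = pj * (digamma(s.M + 1) - digamma(s.M - ys + 1) + np.log1p(-s.p))
        dpj = pj * (ys / s.p - (s.M - ys) / (1.0 - s.p))
        pr.append(pj)
        dM.append(dMj)
        dp.append(dpj)
    return pr, dM, dp


def _conv_all(vecs: list[np.ndarray]) -> np.ndarray:
    out = vecs[0]
    for v in vecs[1:]:
        out = np.convolve(out, v)
    return out


def fisher_information(theta: MixtureParams, mode: str = "observed") -> FisherResult:
    """Single-experiment Fisher information matrix, 2m x 2m.

    ``observed``: information of the summed photon number; derivatives of
    ``L(i) = sum over compositions of i`` obtained by convolving one species'
    score vector with the other species' PMFs.
    ``as_printed``: complete-data form, summing score products of the joint
    composition probability ``f(y) = prod_j pr_j(y_j)`` over every tuple.
    """
    if mode not in ("observed", "as_printed"):
        raise ValueError(f"unknown FIM mode {mode!r}")
    if np.any(theta.ps >= 1.0):
        raise ValueError("Fisher information requires all p strictly inside (0, 1)")
    m = theta.m
    pr, dM, dp = _species_score_vectors(theta)
    if mode == "observed":
        L = _conv_all(pr)
        scores = []
        for j in range(m):
            rest = _conv_all([pr[k] for k in range(m) if k != j]) if m > 1 else None
            for vec in (dM[j], dp[j]):
                scores.append(np.convolve(vec, rest) if rest is not None else vec)
        S = np.stack(scores)  # (2m, M_tot+1)
        ok = L > 0
        I = (S[:, ok] / L[ok][None, :]) @ S[:, ok].T
    else:
        grids = np.array(
            list(itertools.product(*[range(s.M + 1) for s in theta.species])), dtype=np.int64
        ).T  # (m, n_tuples)
        f = np.ones(grids.shape[1])
        for j in range(m):
            f *= pr[j][grids[j]]
        ratios = []
        for j in range(m):
            ratios.append(dM[j][grids[j]] / pr[j][grids[j]])
            ratios.append(dp[j][grids[j]] / pr[j][grids[j]])
        R = np.stack(ratios)  # score of log f
        I = (R * f[None, :]) @ R.T
    I = 0.5 * (I + I.T)
    with np.errstate(all="ignore"):
        cond = np.linalg.cond(I)
    singular = bool((not np.isfinite(cond)) or (1.0 / cond) < _RCOND_SINGULAR)
    return FisherResult(matrix=I, singular=singular)


def crlb_at(theta: MixtureParams, nu: float, mode: str = "observed") -> FisherResult:
    """CRLB for ``nu`` experiments: inverse information scaled by 1/nu."""
    res = fisher_information(theta, mode=mode)
    if res.singular:
        return FisherResult(matrix=res.matrix, singular=True, crlb=None, nu=float(nu))
    crlb = np.linalg.inv(res.matrix) / float(nu)
    return FisherResult(matrix=res.matrix, singular=False, crlb=crlb, nu=float(nu))


def required_nu(
    theta: MixtureParams,
    param_index: int,
    rel_precision: float = 0.01,
    mode: str = "observed",
) -> float:
    """Experiments needed for sqrt(CRLB) of one parameter to reach a relative precision.

    ``param_index`` addresses the flat vector [M_1, p_1, ..., M_m, p_m];
    returns ``inf`` when the information matrix is singular (the bound does
    not exist, e.g. two identical species).
    """
    if rel_precision <= 0:
        raise ValueError("rel_precision must be positive")
    res = fisher_information(theta, mode=mode)
    if res.singular:
        return float("inf")
    C = np.linalg.inv(res.matrix)
    value = theta.to_flat()[param_index]
    return float(C[param_index, param_index] / (rel_precision * value) ** 2)
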