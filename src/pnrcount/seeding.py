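"""Moment-method seeding and the emitter-count combination search.

The mixture likelihood has many local maxima and the number grows quickly
with the number of species, so plain EM from an arbitrary start is
unreliable.  The search exploits that the emitter counts are bounded
integers: every strictly-increasing m-combination ``(M_1 < ... < M_m)`` from
``{1..M_max}`` is enumerated, the sample moments of the histogram are
matched to the model's power sums

    sum_j M_j p_j^k = b_k,   k = 1..m,

to obtain real initial detection probabilities for that combination, and a
fixed-M EM refines each feasible seed.  The fit with the largest
log-likelihood wins.

All feasible candidates are iterated together in a vectorized fixed-M EM so
the search stays cheap even with hundreds of candidates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .em import EMSettings, FitResult, _P_CLAMP, run_em
from .model import MixtureParams, PhotonHistogram, SpeciesParams

__all__ = [
    "MomentSet",
    "SeedCandidate",
    "sample_moments",
    "enumerate_M_combinations",
    "moment_power_sums",
    "solve_moment_system",
    "fit_with_search",
]

# fixed internal seed for the Newton starts of the m>=3 moment solver;
# the search must be reproducible irrespective of any user RNG
_NEWTON_SEED = 20_231_114
_DEDUP_DECIMALS = 6


@dataclass(frozen=True)
class MomentSet:
    """Sample mean and central moments 2-4 of a photon-count histogram."""

    mu1: float
    mu2: float
    mu3: float
    mu4: float


@dataclass(frozen=True)
class SeedCandidate:
    M_combo: tuple[int, ...]
    p_init: tuple[float, ...]
    feasible: bool = True


def sample_moments(hist: PhotonHistogram) -> MomentSet:
    i = np.arange(hist.N + 1, dtype=float)
    w = hist.counts / hist.nu
    mu1 = float(w @ i)
    d = i - mu1
    return MomentSet(mu1, float(w @ d**2), float(w @ d**3), float(w @ d**4))


def enumerate_M_combinations(M_max: int, m: int) -> list[tuple[int, ...]]:
    """All strictly-increasing m-tuples from {1..M_max}, lexicographic order."""
    if not (1 <= m <= M_max):
        raise ValueError(f"need 1 <= m <= M_max, got m={m}, M_max={M_max}")
    return list(itertools.combinations(range(1, M_max + 1), m))


def moment_power_sums(moments: MomentSet) -> np.ndarray:
    """Convert central moments to the power sums b_k = sum_j M_j p_j^k, k=1..4."""
    mu1, mu2, mu3, mu4 = moments.mu1, moments.mu2, moments.mu3, moments.mu4
    return np.array(
        [
            mu1,
            mu1 - mu2,
            0.5 * (2.0 * mu1 - 3.0 * mu2 + mu3),
            (6.0 * mu1 - 11.0 * mu2 + 3.0 * mu2**2 + 6.0 * mu3 - mu4) / 6.0,
        ]
    )


def _accept(p: np.ndarray) -> bool:
    return bool(np.all(p > 0.0) and np.all(p <= 1.0 + 1e-12))


def _dedupe(sols: list[np.ndarray]) -> list[np.ndarray]:
    seen = set()
    out = []
    for p in sols:
        key = tuple(np.round(p, _DEDUP_DECIMALS))
        if key not in seen:
            seen.add(key)
            out.append(np.minimum(p, 1.0))
    return out


def _solve_newton_many(Mcombos: np.ndarray, b: np.ndarray) -> list[list[np.ndarray]]:
    """Multi-start damped Newton on the power-sum residual, batched over combos.

    ``Mcombos`` is (C, m); every combo shares the same fixed set of random
    starts so the search is reproducible.  Returns one (possibly empty)
    de-duplicated solution list per combo.
    """
    C, m = Mcombos.shape
    n_starts = 48
    rng = np.random.default_rng(_NEWTON_SEED)
    starts = rng.uniform(0.01, 0.99, size=(n_starts, m))
    P = np.tile(starts, (C, 1))  # (C*n_starts, m), combo-major
    Mf = np.repeat(Mcombos.astype(float), n_starts, axis=0)
    bt = np.repeat(b[None, :m], C * n_starts, axis=0)
    k = np.arange(1, m + 1, dtype=float)
    ridge = 1e-13 * np.eye(m)[None, :, :]  # keeps tied-p Jacobians solvable

    def _residual_jacobian(P):
        # F[s, k-1] = sum_j M_j P_sj^k - b_k ; J[s, k-1, j] = k M_j P_sj^(k-1)
        B = P.shape[0]
        F = np.empty((B, m))
        J = np.empty((B, m, m))
        pow_prev = np.ones_like(P)  # P^(k-1), built incrementally
        for ki in range(m):
            J[:, ki, :] = k[ki] * Mf * pow_prev
            pow_prev = pow_prev * P
            F[:, ki] = (Mf * pow_prev).sum(axis=1) - bt[:, ki]
        return F, J

    for _ in range(60):
        F, J = _residual_jacobian(P)
        try:
            step = np.linalg.solve(J + ridge, F[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            P = P + rng.normal(scale=1e-3, size=P.shape)
            continue
        step = np.clip(step, -0.25, 0.25)  # damp; the box is (0,1)
        P = P - step
        np.nan_to_num(P, nan=0.5, posinf=0.5, neginf=0.5, copy=False)
        if np.max(np.abs(step)) < 1e-13:
            break
    F, _ = _residual_jacobian(P)
    ok = (
        (np.max(np.abs(F), axis=1) < 1e-9)
        & np.all(P > 0.0, axis=1)
        & np.all(P <= 1.0 + 1e-12, axis=1)
    )
    out: list[list[np.ndarray]] = []
    for c in range(C):
        sl = slice(c * n_starts, (c + 1) * n_starts)
        good = P[sl][ok[sl]]
        if len(good) == 0:
            out.append([])
            continue
        # dedupe on a rounded key but keep the unrounded solutions
        seen: dict[tuple, np.ndarray] = {}
        for row in good:
            key = tuple(np.round(row, _DEDUP_DECIMALS))
            if key not in seen:
                seen[key] = np.minimum(row, 1.0)
        out.append(sorted(seen.values(), key=tuple))
    return out


def solve_moment_system(M_combo: tuple[int, ...], moments: MomentSet) -> list[np.ndarray]:
    """All real solutions p in (0,1]^m of sum_j M_j p_j^k = b_k, k = 1..m.

    m = 1 is closed form, m = 2 reduces to a quadratic by elimination, and
    m >= 3 uses seeded multi-start Newton iteration with de-duplication.  An
    empty list signals that this emitter-count combination cannot reproduce
    the observed moments with admissible probabilities.
    """
    m = len(M_combo)
    if m > 4:
        raise ValueError("moment relations are available for up to four species")
    M = np.asarray(M_combo, dtype=np.int64)
    b = moment_power_sums(moments)
    if m == 1:
        p = b[0] / M[0]
        return [np.array([p])] if _accept(np.array([p])) else []
    if m == 2:
        M1, M2 = float(M[0]), float(M[1])
        b1, b2 = b[0], b[1]
        # eliminate p2 = (b1 - M1 p1)/M2; quadratic in p1
        a_q = M1 * (M1 + M2)
        b_q = -2.0 * b1 * M1
        c_q = b1**2 - b2 * M2
        roots = np.roots([a_q, b_q, c_q])
        sols = []
        for r in roots:
            if abs(r.imag) > 1e-8:
                continue
            p1 = float(r.real)
            p2 = (b1 - M1 * p1) / M2
            p = np.array([p1, p2])
            if _accept(p):
                sols.append(p)
        return _dedupe(sols)
    return _solve_newton_many(M[None, :], b)[0]


def _bconv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise full convolution of two (L, W) batches."""
    L, Wa = a.shape
    Wb = b.shape[1]
    out = np.zeros((L, Wa + Wb - 1))
    for y in range(Wa):
        out[:, y : y + Wb] += a[:, y : y + 1] * b
    return out


def _log_binom_coef(M: np.ndarray, width: int) -> np.ndarray:
    """log C(M, y) for y = 0..width-1 (iteration-invariant, precomputed once)."""
    from scipy.special import gammaln

    y = np.arange(width)[None, :]
    Mf = M[:, None].astype(float)
    return gammaln(Mf + 1) - gammaln(y + 1) - gammaln(np.maximum(Mf - y, 0) + 1)


def _batch_binom_pmf(
    M: np.ndarray, p: np.ndarray, width: int, lbc: np.ndarray | None = None
) -> np.ndarray:
    """Binomial PMFs for a batch of (M, p) pairs on y = 0..width-1 (0 beyond M)."""
    if lbc is None:
        lbc = _log_binom_coef(M, width)
    y = np.arange(width)[None, :]
    Mf = M[:, None].astype(float)
    pc = np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP)[:, None]
    pmf = np.exp(lbc + y * np.log(pc) + (Mf - y) * np.log1p(-pc))
    pmf[y > Mf] = 0.0
    return pmf


def _em_iterate(
    counts: np.ndarray,
    nu: float,
    M: np.ndarray,
    P0: np.ndarray,
    tol_p: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core fixed-M EM loop over a batch of candidates; returns (P, iters, conv).

    Every ``_ACCEL_EVERY`` iterations an Aitken extrapolation of the linearly
    converging p-sequence is attempted per candidate and accepted only when
    it does not decrease that candidate's log-likelihood, which preserves the
    EM ascent guarantee while collapsing slow geometric tails.
    """
    Lc, m = M.shape
    N = len(counts) - 1
    width = N + 1
    yv = np.arange(width)[None, :]
    total_photons = float(counts @ np.arange(width))
    P = np.clip(P0, _P_CLAMP, 1.0 - _P_CLAMP).copy()
    iters = np.zeros(Lc, dtype=np.int64)
    conv = np.zeros(Lc, dtype=bool)
    active = np.arange(Lc)
    lbc_all = [_log_binom_coef(M[:, j], width) for j in range(m)]
    obs = counts > 0
    c_obs = counts[obs]

    def _pmfs(Ma, Pa, lbc):
        return [_batch_binom_pmf(Ma[:, j], Pa[:, j], width, lbc[j]) for j in range(m)]

    def _mix(pmfs):
        L_all = pmfs[0]
        for q in pmfs[1:]:
            L_all = _bconv(L_all, q)[:, :width]
        return L_all

    def _ll_of(L_all):
        with np.errstate(divide="ignore"):
            logL = np.where(L_all > 0, np.log(np.where(L_all > 0, L_all, 1.0)), -np.inf)
        return logL[:, obs] @ c_obs

    P_prev = None
    for it in range(1, max_iter + 1):
        Ma, Pa = M[active], P[active]
        lbc = [lbc_all[j][active] for j in range(m)]
        pmfs = _pmfs(Ma, Pa, lbc)
        P_new = np.empty_like(Pa)
        if m == 1:
            # single species takes every photon: closed form, converges at once
            P_new[:, 0] = total_photons / (Ma[:, 0] * nu)
        else:
            L_all = _mix(pmfs)
            acc = np.zeros(len(active))
            for j in range(m - 1):
                # leave-one-out convolution truncated to the observed support
                rest = None
                for k2 in range(m):
                    if k2 == j:
                        continue
                    rest = pmfs[k2] if rest is None else _bconv(rest, pmfs[k2])[:, :width]
                numer = _bconv(yv * pmfs[j], rest)[:, :width]
                with np.errstate(invalid="ignore", divide="ignore"):
                    Ebar = np.where(L_all > 0, numer / np.where(L_all > 0, L_all, 1.0), 0.0)
                Sj = Ebar @ counts
                P_new[:, j] = Sj / (Ma[:, j] * nu)
                acc += Sj
            P_new[:, m - 1] = (total_photons - acc) / (Ma[:, m - 1] * nu)
        P_new = np.clip(P_new, _P_CLAMP, 1.0 - _P_CLAMP)

        if m > 1 and P_prev is not None and it % _ACCEL_EVERY == 0:
            d1 = P_new - Pa
            d0 = Pa - P_prev[active]
            with np.errstate(invalid="ignore", divide="ignore"):
                rho = np.where(np.abs(d0) > 1e-15, d1 / np.where(d0 != 0, d0, 1.0), 0.0)
            valid = (rho > 0.0) & (rho < 0.9999)
            denom = np.where(valid, 1.0 - rho, 1.0)
            P_acc = np.where(valid, P_new + d1 * rho / denom, P_new)
            P_acc = np.clip(P_acc, _P_CLAMP, 1.0 - _P_CLAMP)
            ll_new = _ll_of(_mix(_pmfs(Ma, P_new, lbc)))
            ll_acc = _ll_of(_mix(_pmfs(Ma, P_acc, lbc)))
            take = ll_acc >= ll_new
            P_new[take] = P_acc[take]

        dp = np.max(np.abs(P_new - Pa), axis=1)
        if P_prev is None:
            P_prev = P.copy()
        P_prev[active] = Pa
        P[active] = P_new
        done = dp < tol_p
        iters[active] = it
        conv[active[done]] = True
        active = active[~done]
        if len(active) == 0:
            break
    return P, iters, conv


def _batch_loglik(counts: np.ndarray, M: np.ndarray, P: np.ndarray) -> np.ndarray:
    Lc, m = M.shape
    width = len(counts)
    obs = counts > 0
    ll = np.empty(Lc)
    for start in range(0, Lc, 512):
        sl = slice(start, min(start + 512, Lc))
        pmfs = [_batch_binom_pmf(M[sl, j], P[sl, j], width) for j in range(m)]
        L_all = pmfs[0]
        for q in pmfs[1:]:
            L_all = _bconv(L_all, q)[:, :width]
        with np.errstate(divide="ignore"):
            logL = np.where(L_all > 0, np.log(np.where(L_all > 0, L_all, 1.0)), -np.inf)
        ll[sl] = (logL[:, obs] * counts[obs][None, :]).sum(axis=1)
    return ll


# Candidates this far below the running best log-likelihood after the loose
# first pass cannot overtake the winner during tolerance tightening: with
# max |dp| < 1e-6 per iteration the remaining likelihood gain is O(nu * dp^2).
_SCREEN_LL_MARGIN = 50.0
_PHASE1_TOL = 1e-6
_PHASE1_MAX_ITER = 1500
_ACCEL_EVERY = 20


def _batched_fixed_M_em(
    counts: np.ndarray,
    nu: float,
    M: np.ndarray,
    P0: np.ndarray,
    settings: EMSettings,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-M EM run simultaneously for L candidates.

    Parameters: counts (N+1,), M (L, m) integer combos, P0 (L, m) initial
    probabilities.  Returns (P, loglik, iterations, converged) arrays.
    Agrees (to tolerance) with per-candidate ``run_em`` in ``fix_M`` mode.

    Two phases: a loose pass over every candidate, then full-tolerance
    refinement restricted to the likelihood-competitive ones — the rest are
    provably out of the running (see ``_SCREEN_LL_MARGIN``).
    """
    tol1 = max(settings.tol_p, _PHASE1_TOL)
    it1_max = min(settings.max_iter, _PHASE1_MAX_ITER)
    P, iters, conv = _em_iterate(counts, nu, M, P0, tol1, it1_max)
    ll = _batch_loglik(counts, M, P)
    if settings.tol_p >= tol1 and settings.max_iter <= it1_max:
        return P, ll, iters, conv
    keep = np.nonzero(ll >= ll.max() - _SCREEN_LL_MARGIN)[0]
    conv[:] = False  # only refined candidates can claim full-tolerance convergence
    P2, it2, conv2 = _em_iterate(
        counts, nu, M[keep], P[keep], settings.tol_p, settings.max_iter - iters[keep].min()
    )
    P[keep] = P2
    iters[keep] = iters[keep] + it2
    conv[keep] = conv2
    ll[keep] = _batch_loglik(counts, M[keep], P[keep])
    return P, ll, iters, conv


def fit_with_search(
    hist: PhotonHistogram,
    m: int,
    M_max: int | None = None,
    settings: EMSettings | None = None,
    refine: bool = False,
) -> FitResult:
    """Estimate an m-species mixture by moment-seeded combination search.

    Every strictly-increasing emitter-count combination from ``{1..M_max}``
    whose total covers the observed support is seeded by the moment solver;
    each real seed is refined by fixed-M EM and the largest final
    log-likelihood wins (ties break to the lexicographically smallest
    combination, then the smallest seed).  Set ``refine=True`` to polish the
    winner with a final free-M EM pass.
    """
    if M_max is None:
        M_max = max(20, hist.N)
    if m > M_max:
        raise ValueError(f"m={m} exceeds M_max={M_max}")
    settings = settings or EMSettings(fix_M=True)
    moments = sample_moments(hist)

    combos = [c for c in enumerate_M_combinations(M_max, m) if sum(c) >= hist.N]
    # combos whose total misses the observed support are dropped: zero likelihood
    if m >= 3:
        sols_per_combo = _solve_newton_many(
            np.array(combos, dtype=np.int64), moment_power_sums(moments)
        )
    else:
        sols_per_combo = [solve_moment_system(c, moments) for c in combos]
    candidates: list[SeedCandidate] = []
    for combo, sols in zip(combos, sols_per_combo):
        for p0 in sols:
            candidates.append(SeedCandidate(combo, tuple(float(x) for x in p0)))
    if not candidates:
        raise RuntimeError(
            "no feasible seed: no emitter-count combination admits a real "
            "moment solution covering the observed support"
        )
    candidates.sort(key=lambda c: (c.M_combo, c.p_init))
    Mb = np.array([c.M_combo for c in candidates], dtype=np.int64)
    P0 = np.array([c.p_init for c in candidates])
    P, ll, iters, conv = _batched_fixed_M_em(hist.counts, hist.nu, Mb, P0, settings)
    win = int(np.argmax(ll))  # first max: candidates pre-sorted for the tie-break
    theta_hat = MixtureParams(
        tuple(
            SpeciesParams(int(Mi), float(pi)) for Mi, pi in zip(Mb[win], P[win])
        )
    )
    result = FitResult(
        theta_hat=theta_hat,
        loglik=float(ll[win]),
        converged=bool(conv[win]),
        iterations=int(iters[win]),
        seed_provenance=(
            f"moment-seeded search: M={candidates[win].M_combo}, "
            f"p0={tuple(round(x, 6) for x in candidates[win].p_init)}, "
            f"{len(candidates)} candidates"
        ),
    )
    if refine:
        free = EMSettings(
            tol_p=settings.tol_p,
            tol_ll=settings.tol_ll,
            max_iter=settings.max_iter,
            M_max=M_max,
            fix_M=False,
        )
        polished = run_em(hist, result.theta_hat, free, seed_provenance=result.seed_provenance)
        if polished.loglik >= result.loglik:
            result = polished
    return result
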