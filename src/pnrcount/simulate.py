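"""Synthetic photon-number-resolving detector (PNRD) data.

Two statistically equivalent sampling modes are provided:

``per_shot``
    Realizes the generative story literally: each of the ``nu`` pulses draws
    one binomial photon number per species and records their sum.  Cost is
    linear in ``nu``, so it is guarded to ``nu <= 1e7``.

``multinomial``
    Draws the bin occupancies of the whole histogram in one multinomial step
    with cell probabilities given by the model PMF.  Since the estimator only
    ever sees the histogram ``[C_0..C_N]``, this is statistically identical
    to ``nu`` independent experiments and remains cheap up to ``nu = 1e14``,
    the regime the three-species experiments require.  It is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import MixtureParams, PhotonHistogram, mixture_pmf

__all__ = ["SimConfig", "sample_histogram"]

_PER_SHOT_CAP = 10**7


@dataclass(frozen=True)
class SimConfig:
    theta: MixtureParams
    nu: int
    seed: int
    mode: str = "multinomial"

    def __post_init__(self) -> None:
        if self.nu < 1:
            raise ValueError("nu must be >= 1")
        if self.mode not in ("per_shot", "multinomial"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "per_shot" and self.nu > _PER_SHOT_CAP:
            raise ValueError(
                f"per_shot mode is limited to nu <= {_PER_SHOT_CAP:.0e}; "
                "use multinomial mode for larger runs"
            )


def sample_histogram(cfg: SimConfig) -> PhotonHistogram:
    """Draw one synthetic histogram; deterministic given ``cfg.seed``.

    The returned histogram satisfies ``sum(C_i) == nu`` exactly and its
    support lies within ``0..M_total``.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.mode == "per_shot":
        totals = np.zeros(cfg.nu, dtype=np.int64)
        for s in cfg.theta.species:
            totals += rng.binomial(s.M, s.p, size=cfg.nu)
        counts = np.bincount(totals, minlength=cfg.theta.M_total + 1)
    else:
        pmf = mixture_pmf(cfg.theta)
        # guard tiny negative round-off before renormalizing the cell vector
        pmf = np.clip(pmf, 0.0, None)
        counts = rng.multinomial(cfg.nu, pmf / pmf.sum())
    return PhotonHistogram(counts.astype(float))
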