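"""Linear-quadratic survival, EUD, and EQD2.

The core quantities:

*   cell survival after a single dose ``d``: ``SF(d) = exp(-alpha*d - beta*d**2)``;
*   the survival-weighted mean over a DVH, ``S_bar = sum_i nu_i * SF(d_i)``;
*   the equivalent uniform dose (EUD), the unique uniform dose with
    ``SF(EUD) = S_bar`` — solved in closed form from the LQ quadratic;
*   the equivalent dose in 2 Gy fractions: a fraction whose (uniform or
    equivalent-uniform) dose is ``e`` contributes
    ``e * (e + alpha/beta) / (2 + alpha/beta)`` Gy of EQD2, and fractions add.

A regimen opening with one heterogeneous stepwise-gradient fraction and
continuing with ``n - 1`` uniform fractions therefore has

    EQD2 = f(EUD_gradient) + (n - 1) * f(EUD_uniform),

with ``f`` the per-fraction conversion above; the conventional comparator is
``n * f(EUD_uniform)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from stepgrad.dvh import DVH


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic model parameters.

    Defaults are the tumor values used throughout this package:
    alpha = 0.3 / Gy, beta = 0.03 / Gy^2 (hence alpha/beta = 10 Gy), with a
    30% relative standard uncertainty on each for Monte Carlo propagation.
    """

    alpha: float = 0.3
    beta: float = 0.03
    cv: float = 0.30

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")

    @property
    def alpha_beta(self) -> float:
        """The alpha/beta ratio, Gy (infinite for beta = 0)."""
        return self.alpha / self.beta if self.beta > 0 else np.inf


def survival_fraction(d, params: LQParams = LQParams()):
    """LQ surviving fraction after a single uniform dose ``d`` (Gy)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = np.exp(-params.alpha * d - params.beta * d * d)
    return float(out) if out.ndim == 0 else out


def _log_mean_survival(dvh: DVH, params: LQParams) -> float:
    """log of the DVH-weighted mean survival, computed stably.

    Accumulated with logsumexp so that high-dose bins whose SF underflows in
    linear space still contribute correctly.
    """
    d = dvh.bin_dose
    nu = dvh.bin_fraction
    mask = nu > 0
    log_terms = np.log(nu[mask]) - params.alpha * d[mask] - params.beta * d[mask] ** 2
    return float(logsumexp(log_terms))


def mean_survival(dvh: DVH, params: LQParams = LQParams()) -> float:
    """Volume-weighted mean surviving fraction over a DVH."""
    return float(np.exp(_log_mean_survival(dvh, params)))


def eud(dvh: DVH, params: LQParams = LQParams()) -> float:
    """Equivalent uniform dose of a DVH, Gy.

    The uniform dose producing the same mean survival as the heterogeneous
    distribution: the non-negative root of
    ``alpha*d + beta*d**2 = -ln(S_bar)``. A single-bin (uniform) DVH returns
    its dose exactly, independent of the parameters.
    """
    carrying = dvh.bin_dose[dvh.bin_fraction > 0]
    if carrying.size == 1:
        return float(carrying[0])
    L = -_log_mean_survival(dvh, params)
    return _eud_from_log_kill(L, params)


def _eud_from_log_kill(L: float, params: LQParams) -> float:
    if L < 0:
        # Mean survival > 1 cannot arise from non-negative doses.
        if L > -1e-12:
            return 0.0
        raise ValueError(f"mean survival exceeds 1 (log kill {L:.3g})")
    if params.beta == 0:
        return L / params.alpha
    a, b = params.alpha, params.beta
    return (-a + np.sqrt(a * a + 4.0 * b * L)) / (2.0 * b)


def eqd2_per_fraction(eud_fr: float, params: LQParams = LQParams()) -> float:
    """EQD2 contributed by one fraction of (equivalent uniform) dose ``eud_fr``.

    ``eud_fr * (eud_fr + alpha/beta) / (2 + alpha/beta)``; a 2 Gy fraction
    maps to exactly 2 Gy.
    """
    if eud_fr < 0:
        raise ValueError(f"eud must be >= 0, got {eud_fr}")
    ab = params.alpha_beta
    if np.isinf(ab):  # beta = 0: fractionation-insensitive limit
        return eud_fr
    return eud_fr * (eud_fr + ab) / (2.0 + ab)


def eqd2_conventional(eud_c: float, n: int, params: LQParams = LQParams()) -> float:
    """Total EQD2 of a conventional regimen: ``n`` identical uniform fractions."""
    if n < 1:
        raise ValueError(f"fraction count must be >= 1, got {n}")
    return n * eqd2_per_fraction(eud_c, params)


def eqd2_stepwise(
    eud_gradient: float, eud_c: float, n: int, params: LQParams = LQParams()
) -> float:
    """Total EQD2 of a stepwise-gradient regimen.

    One heterogeneous gradient fraction (EUD ``eud_gradient``) followed by
    ``n - 1`` conventional uniform fractions (EUD ``eud_c``); ``n`` is the
    total fraction count. Reduces exactly to :func:`eqd2_conventional` when
    the two EUDs coincide.
    """
    if n < 1:
        raise ValueError(f"fraction count must be >= 1, got {n}")
    return eqd2_per_fraction(eud_gradient, params) + (n - 1) * eqd2_per_fraction(
        eud_c, params
    )


def total_eqd2(per_fraction: list[tuple[float, int]]) -> float:
    """Sum per-fraction EQD2 contributions over phases.

    ``per_fraction`` is a list of ``(eqd2_per_fraction_gy, fraction_count)``
    pairs; phases add because EQD2 is additive across fractions. Covers
    regimens with any number of phases (e.g. a third boost phase).
    """
    if not per_fraction:
        raise ValueError("at least one phase is required")
    total = 0.0
    for eqd2_fr, count in per_fraction:
        if count < 1:
            raise ValueError(f"fraction count must be >= 1, got {count}")
        if eqd2_fr < 0:
            raise ValueError(f"per-fraction EQD2 must be >= 0, got {eqd2_fr}")
        total += count * eqd2_fr
    return total


def eud_from_eqd2(eqd2_fr: float, params: LQParams = LQParams()) -> float:
    """Invert the per-fraction EQD2 conversion back to an EUD.

    Positive root of ``e**2 + (alpha/beta)*e - eqd2_fr*(2 + alpha/beta) = 0``;
    the forward map :func:`eqd2_per_fraction` reproduces the input.
    """
    if eqd2_fr < 0:
        raise ValueError(f"eqd2 must be >= 0, got {eqd2_fr}")
    ab = params.alpha_beta
    if np.isinf(ab):
        return eqd2_fr
    return 0.5 * (-ab + np.sqrt(ab * ab + 4.0 * eqd2_fr * (2.0 + ab)))
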