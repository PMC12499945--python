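"""Multi-phase regimens and their EUD/EQD2 analysis."""

from __future__ import annotations

from dataclasses import dataclass

from stepgrad.dvh import DVH
from stepgrad.lq import LQParams, eud, eqd2_per_fraction, total_eqd2
from stepgrad.cohort import relative_difference


@dataclass(frozen=True)
class Regimen:
    """An ordered list of treatment phases.

    Each phase is a ``(DVH, fraction_count)`` pair: every fraction in a phase
    delivers the phase's dose distribution once. A stepwise-gradient regimen
    is typically one heterogeneous phase of a single fraction followed by a
    uniform phase; a conventional regimen is a single uniform phase.
    """

    phases: tuple[tuple[DVH, int], ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("a regimen needs at least one phase")
        phases = tuple((dvh, int(n)) for dvh, n in self.phases)
        for _, n in phases:
            if n < 1:
                raise ValueError(f"fraction count must be >= 1, got {n}")
        object.__setattr__(self, "phases", phases)

    @property
    def n_fractions(self) -> int:
        return sum(n for _, n in self.phases)


@dataclass(frozen=True)
class PhaseResult:
    """Per-phase analysis: EUD and its per-fraction EQD2, both Gy."""

    eud: float
    eqd2_per_fraction: float
    fraction_count: int


@dataclass(frozen=True)
class RegimenResult:
    """Full-regimen analysis; ``total_eqd2`` is the sum of per-fraction
    EQD2 over all fractions of all phases."""

    total_eqd2: float
    per_phase: tuple[PhaseResult, ...]

    @property
    def first_fraction_eqd2(self) -> float:
        return self.per_phase[0].eqd2_per_fraction


def analyze_regimen(regimen: Regimen, params: LQParams = LQParams()) -> RegimenResult:
    """Compute per-phase EUD / per-fraction EQD2 and the regimen total."""
    per_phase = []
    for dvh, count in regimen.phases:
        e = eud(dvh, params)
        per_phase.append(PhaseResult(e, eqd2_per_fraction(e, params), count))
    total = total_eqd2([(p.eqd2_per_fraction, p.fraction_count) for p in per_phase])
    return RegimenResult(total_eqd2=total, per_phase=tuple(per_phase))


def compare_regimens(
    test: Regimen, reference: Regimen, params: LQParams = LQParams()
) -> dict:
    """Compare two regimens on the EQD2 scale.

    Returns the two :class:`RegimenResult` objects plus the percent excess of
    ``test`` over ``reference`` for the first fraction alone
    (``delta_first_fraction``) and for the whole course (``delta_total``).
    """
    res_test = analyze_regimen(test, params)
    res_ref = analyze_regimen(reference, params)
    return {
        "test": res_test,
        "reference": res_ref,
        "delta_first_fraction": relative_difference(
            res_test.first_fraction_eqd2, res_ref.first_fraction_eqd2
        ),
        "delta_total": relative_difference(res_test.total_eqd2, res_ref.total_eqd2),
    }
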