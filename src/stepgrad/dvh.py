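"""Dose-volume histograms.

A differential DVH stores, for a single structure (e.g. a PTV), the relative
volume fraction receiving each dose level. Only relative fractions are kept:
under the assumption of uniform cell density, absolute volume and cell number
cancel out of every survival-weighted quantity downstream, so the histogram
of volume fractions is the complete input to the radiobiological analysis.

Planning systems usually export *cumulative* DVHs (fraction of volume
receiving at least a given dose); :func:`DVH.from_cumulative` converts, using
the interval midpoint as the representative dose of each bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

# Inputs whose fractions sum to 1 within this are renormalized with a warning;
# anything worse is rejected as a malformed histogram.
_SUM_TOLERANCE = 1e-3


class DVHValidationError(ValueError):
    """Raised when a dose-volume histogram violates its invariants."""


@dataclass(frozen=True)
class DVH:
    """Differential dose-volume histogram.

    Parameters
    ----------
    bin_dose
        Representative dose of each bin, Gy, strictly increasing.
    bin_fraction
        Relative volume fraction per bin; non-negative, summing to 1
        (inputs off by less than 1e-3 are renormalized with a warning).
    bin_width
        Optional bin widths, Gy (metadata; not used in the survival math).
    label
        Free-text structure name, e.g. ``"PTV"``.
    volume_cc
        Optional absolute structure volume in cm^3 (metadata only).
    """

    bin_dose: np.ndarray
    bin_fraction: np.ndarray
    bin_width: np.ndarray | None = None
    label: str = ""
    volume_cc: float | None = None

    def __post_init__(self) -> None:
        dose = np.atleast_1d(np.asarray(self.bin_dose, dtype=float))
        frac = np.atleast_1d(np.asarray(self.bin_fraction, dtype=float))
        if dose.shape != frac.shape or dose.ndim != 1:
            raise DVHValidationError(
                f"bin_dose and bin_fraction must be 1-D and equal length; "
                f"got shapes {dose.shape} and {frac.shape}"
            )
        if dose.size == 0:
            raise DVHValidationError("empty histogram")
        neg = np.flatnonzero(dose < 0)
        if neg.size:
            raise DVHValidationError(f"negative dose at bin {neg[0]}: {dose[neg[0]]}")
        neg = np.flatnonzero(frac < 0)
        if neg.size:
            raise DVHValidationError(
                f"negative volume fraction at bin {neg[0]}: {frac[neg[0]]}"
            )
        bad = np.flatnonzero(np.diff(dose) <= 0)
        if bad.size:
            raise DVHValidationError(
                f"bin_dose not strictly increasing at index {bad[0] + 1}"
            )
        total = frac.sum()
        if total <= 0:
            raise DVHValidationError("all volume fractions are zero")
        if abs(total - 1.0) > _SUM_TOLERANCE:
            raise DVHValidationError(
                f"volume fractions sum to {total:.6g}, outside the "
                f"{_SUM_TOLERANCE:g} renormalization tolerance"
            )
        if abs(total - 1.0) > 1e-9:
            logger.warning(
                "DVH %r fractions sum to %.6g; renormalizing", self.label, total
            )
        frac = frac / total
        object.__setattr__(self, "bin_dose", dose)
        object.__setattr__(self, "bin_fraction", frac)
        if self.bin_width is not None:
            w = np.broadcast_to(
                np.asarray(self.bin_width, dtype=float), dose.shape
            ).copy()
            object.__setattr__(self, "bin_width", w)

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_cumulative(
        cls,
        dose_points: np.ndarray,
        cum_fraction: np.ndarray,
        label: str = "",
        volume_cc: float | None = None,
    ) -> "DVH":
        """Build a differential DVH from a cumulative one.

        ``dose_points`` are ascending edge doses; ``cum_fraction[i]`` is the
        volume fraction receiving at least ``dose_points[i]`` and must start
        at 1 and be non-increasing. Each interval becomes one bin at its
        midpoint with fraction equal to the cumulative decrement.
        """
        dose = np.asarray(dose_points, dtype=float)
        cum = np.asarray(cum_fraction, dtype=float)
        if dose.shape != cum.shape or dose.ndim != 1 or dose.size < 2:
            raise DVHValidationError(
                f"need equal-length 1-D arrays with >= 2 points; "
                f"got shapes {dose.shape} and {cum.shape}"
            )
        bad = np.flatnonzero(np.diff(dose) <= 0)
        if bad.size:
            raise DVHValidationError(
                f"dose_points not strictly ascending at index {bad[0] + 1}"
            )
        bad = np.flatnonzero(np.diff(cum) > 0)
        if bad.size:
            raise DVHValidationError(
                f"cum_fraction increases at index {bad[0] + 1}"
            )
        if abs(cum[0] - 1.0) > 1e-6:
            raise DVHValidationError(
                f"cumulative fraction must start at 1, got {cum[0]:.6g}"
            )
        mid = 0.5 * (dose[:-1] + dose[1:])
        frac = -np.diff(cum)
        # Volume still receiving >= the last dose point is carried in a
        # terminal bin at that dose.
        if cum[-1] > 1e-12:
            mid = np.append(mid, dose[-1])
            frac = np.append(frac, cum[-1])
        keep = frac > 0
        if not keep.any():
            raise DVHValidationError("cumulative histogram carries no volume")
        return cls(
            bin_dose=mid[keep],
            bin_fraction=frac[keep],
            bin_width=None,
            label=label,
            volume_cc=volume_cc,
        )

    # -- conversions and statistics --------------------------------------

    def to_cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative view: (dose, fraction of volume receiving >= dose).

        Returned at the bin doses themselves; the first fraction is 1.
        """
        cum = 1.0 - np.concatenate(([0.0], np.cumsum(self.bin_fraction)[:-1]))
        return self.bin_dose.copy(), cum

    def normalized(self) -> "DVH":
        """Return a copy with fractions rescaled to sum to exactly 1."""
        return replace(self, bin_fraction=self.bin_fraction / self.bin_fraction.sum())

    @property
    def mean_dose(self) -> float:
        """Volume-weighted mean dose, Gy."""
        return float(np.dot(self.bin_fraction, self.bin_dose))

    @property
    def min_dose(self) -> float:
        """Lowest dose carrying volume, Gy."""
        return float(self.bin_dose[self.bin_fraction > 0][0])

    @property
    def max_dose(self) -> float:
        """Highest dose carrying volume, Gy."""
        return float(self.bin_dose[self.bin_fraction > 0][-1])

    @property
    def n_bins(self) -> int:
        return int(self.bin_dose.size)


def read_dvh(path) -> DVH:
    """Read a DVH from the package's two-column text dialect.

    The file starts with a header line ``# dvh: differential`` or
    ``# dvh: cumulative`` (an optional ``label=<name>`` may follow on the
    same line), then whitespace- or comma-delimited rows of
    ``dose_gy  fraction``. Cumulative files are converted on read.
    """
    with open(path) as fh:
        header = fh.readline().strip().lower()
        if not header.startswith("#") or "dvh:" not in header:
            raise DVHValidationError(
                f"{path}: first line must declare '# dvh: differential' "
                f"or '# dvh: cumulative'"
            )
        if "cumulative" in header:
            kind = "cumulative"
        elif "differential" in header:
            kind = "differential"
        else:
            raise DVHValidationError(f"{path}: unrecognized DVH kind in {header!r}")
        label = ""
        if "label=" in header:
            label = header.split("label=", 1)[1].strip()
        body = fh.read().replace(",", " ")
    try:
        data = np.loadtxt(body.splitlines(), ndmin=2)
    except ValueError as exc:
        raise DVHValidationError(f"{path}: could not parse numeric rows: {exc}") from exc
    if data.shape[1] != 2:
        raise DVHValidationError(
            f"{path}: expected two columns (dose_gy, fraction), got {data.shape[1]}"
        )
    if kind == "cumulative":
        return DVH.from_cumulative(data[:, 0], data[:, 1], label=label)
    return DVH(bin_dose=data[:, 0], bin_fraction=data[:, 1], label=label)


def write_dvh(dvh: DVH, path, kind: str = "differential") -> None:
    """Write a DVH in the dialect understood by :func:`read_dvh`."""
    if kind == "differential":
        cols = np.column_stack([dvh.bin_dose, dvh.bin_fraction])
    elif kind == "cumulative":
        cols = np.column_stack(dvh.to_cumulative())
    else:
        raise ValueError(f"kind must be 'differential' or 'cumulative', got {kind!r}")
    header = f"# dvh: {kind}" + (f" label={dvh.label}" if dvh.label else "")
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, cols, fmt="%.10g")
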