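"""Synthetic dose distributions emulating stepwise-gradient plans.

No patient DVHs are published for this kind of treatment, so everything
downstream is exercised on synthetic plans built to the same prescription
structure: nested concentric target volumes with stepwise-escalated doses —
an outer shell near conventional dose (2-5 Gy), an intermediate shell
(4-9 Gy) and an inner ablative core (6-12 Gy), delivered in a single first
fraction, followed by uniform conventional fractions to the outer volume.

Two generators produce DVHs:

* a histogram-space mixture model (:func:`make_stepwise_dvh`) — each shell
  contributes its volume fraction as a Gaussian around the shell dose,
  widened by boundary-gradient smearing and intra-shell noise;
* a voxelized concentric-sphere phantom (:func:`dvh_from_grid`) — doses are
  assigned on a 3-D grid from a radial profile and histogrammed, exercising
  the geometric route a planning system would take.

:func:`make_synthetic_cohort` assembles whole regimens (gradient vs
conventional comparator) at cohort scale with schedules drawn from the
clinically used range (1 gradient + 4-27 conventional fractions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from stepgrad.dvh import DVH
from stepgrad.regimen import Regimen


@dataclass(frozen=True)
class StepwisePlanSpec:
    """Parameters of a synthetic stepwise-gradient single-fraction plan.

    ``shell_doses`` are ordered outermost first and non-decreasing inward;
    the defaults (3/9/12 Gy at volume fractions 0.5/0.3/0.2) follow the
    standard prescription pattern. ``transition_width`` models the dose
    gradient at shell boundaries and ``noise_sd`` residual intra-shell
    heterogeneity, both as Gaussian smearing in dose (Gy).
    """

    shell_doses: tuple[float, ...] = (3.0, 9.0, 12.0)
    shell_fractions: tuple[float, ...] = (0.5, 0.3, 0.2)
    transition_width: float = 0.5
    noise_sd: float = 0.2
    seed: int | None = None
    n_voxels: int = 20_000
    bin_width: float = 0.05

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.shell_doses)
        fracs = tuple(float(f) for f in self.shell_fractions)
        if not doses or len(doses) != len(fracs):
            raise ValueError("shell_doses and shell_fractions must be non-empty and equal length")
        if any(np.diff(doses) < 0):
            raise ValueError("shell_doses must be non-decreasing (outermost first)")
        if any(f <= 0 for f in fracs):
            raise ValueError("shell_fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"shell_fractions must sum to 1, got {sum(fracs):.6g}")
        if self.transition_width < 0 or self.noise_sd < 0:
            raise ValueError("transition_width and noise_sd must be >= 0")
        object.__setattr__(self, "shell_doses", doses)
        object.__setattr__(self, "shell_fractions", fracs)


@dataclass(frozen=True)
class SphericalGridSpec:
    """Concentric-sphere phantom on a cubic dose grid.

    ``radii`` are in cm, strictly decreasing inward; ``shell_doses`` gives
    the piecewise-constant radial dose, outermost shell first. The default
    0.3 cm spacing matches typical dose-calculation grid resolution.
    """

    radii: tuple[float, ...] = (3.0, 2.0, 1.0)
    shell_doses: tuple[float, ...] = (3.0, 9.0, 12.0)
    grid_spacing: float = 0.3
    bin_width: float = 0.05

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        if any(np.diff(radii) >= 0):
            raise ValueError("radii must be strictly decreasing inward")
        if radii[-1] <= 0:
            raise ValueError("radii must be positive")
        if len(self.shell_doses) != len(radii):
            raise ValueError("need one shell dose per radius")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")
        object.__setattr__(self, "radii", radii)


def _histogram_dvh(doses: np.ndarray, bin_width: float, label: str) -> DVH:
    doses = np.clip(doses, 0.0, None)
    edges = np.arange(0.0, doses.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(doses, bins=edges)
    mid = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    return DVH(bin_dose=mid[keep], bin_fraction=counts[keep] / counts.sum(), label=label)


def make_stepwise_dvh(spec: StepwisePlanSpec) -> DVH:
    """Differential DVH of a synthetic stepwise-gradient fraction.

    With zero smearing and noise the DVH has exactly one bin per distinct
    shell dose; otherwise shell membership is sampled by volume fraction and
    each voxel dose drawn from a Gaussian around its shell dose (total sigma
    combining transition smearing and noise in quadrature), truncated at 0.
    """
    doses = np.asarray(spec.shell_doses)
    fracs = np.asarray(spec.shell_fractions)
    sigma = float(np.hypot(spec.transition_width, spec.noise_sd))
    if sigma == 0.0:
        uniq, inv = np.unique(doses, return_inverse=True)
        agg = np.zeros_like(uniq)
        np.add.at(agg, inv, fracs)
        return DVH(bin_dose=uniq, bin_fraction=agg, label="stepwise")
    rng = np.random.default_rng(spec.seed)
    shell = rng.choice(doses.size, size=spec.n_voxels, p=fracs)
    voxel_dose = rng.normal(doses[shell], sigma)
    return _histogram_dvh(voxel_dose, spec.bin_width, "stepwise")


def make_uniform_dvh(
    dose: float,
    heterogeneity_sd: float = 0.0,
    seed: int | None = None,
    n_voxels: int = 20_000,
    bin_width: float = 0.02,
) -> DVH:
    """DVH of a near-uniform conventional fraction.

    ``heterogeneity_sd = 0`` gives a single bin at the prescription dose
    (EUD equals the dose exactly); otherwise voxel doses are Gaussian around
    the prescription.
    """
    if dose <= 0:
        raise ValueError(f"dose must be > 0, got {dose}")
    if heterogeneity_sd < 0:
        raise ValueError(f"heterogeneity_sd must be >= 0, got {heterogeneity_sd}")
    if heterogeneity_sd == 0.0:
        return DVH(bin_dose=[dose], bin_fraction=[1.0], label="uniform")
    rng = np.random.default_rng(seed)
    voxel_dose = rng.normal(dose, heterogeneity_sd, n_voxels)
    return _histogram_dvh(voxel_dose, bin_width, "uniform")


def dvh_from_grid(spec: SphericalGridSpec) -> DVH:
    """DVH from a voxelized concentric-sphere phantom.

    Voxel centers on a cubic grid inside the outer sphere are assigned the
    dose of the innermost sphere that contains them; the DVH is their
    histogram. Shell volume fractions converge to the analytic sphere-shell
    ratios as the grid is refined.
    """
    r_outer = spec.radii[0]
    h = spec.grid_spacing
    coords = np.arange(-r_outer + h / 2, r_outer, h)
    x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
    r = np.sqrt(x * x + y * y + z * z).ravel()
    inside = r <= r_outer
    if not inside.any():
        raise ValueError("grid too coarse: no voxels inside the outer sphere")
    r = r[inside]
    dose = np.full(r.size, spec.shell_doses[0], dtype=float)
    # innermost containing sphere wins: iterate inward
    for radius, d in zip(spec.radii[1:], spec.shell_doses[1:]):
        dose[r <= radius] = d
    return _histogram_dvh(dose, spec.bin_width, "grid")


@dataclass(frozen=True)
class SyntheticCase:
    """One synthetic cohort entry: gradient regimen, comparator, metadata."""

    gradient: Regimen
    conventional: Regimen
    meta: dict = field(default_factory=dict)


def make_synthetic_cohort(
    n_cases: int,
    seed: int | None = None,
    transition_width: float = 0.5,
    noise_sd: float = 0.2,
    conventional_heterogeneity_sd: float = 0.05,
) -> list[SyntheticCase]:
    """Generate a reproducible synthetic cohort of paired regimens.

    Each case draws a schedule of 1 gradient + k conventional fractions with
    k in 4..27, an outer-shell dose in 2-5 Gy (quarter-Gy steps),
    intermediate and inner doses escalating into the 4-9 and 6-12 Gy bands,
    and shell volume fractions scattered around the 0.5/0.3/0.2 default.
    The conventional comparator delivers the outer dose uniformly in k+1
    fractions.
    """
    if n_cases < 1:
        raise ValueError(f"n_cases must be >= 1, got {n_cases}")
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        k = int(rng.integers(4, 28))
        outer = float(rng.choice(np.arange(2.0, 5.25, 0.25)))
        intermediate = float(np.round(rng.uniform(max(outer + 1.0, 4.0), 9.0), 1))
        inner = float(np.round(rng.uniform(max(intermediate, 6.0), 12.0), 1))
        fracs = rng.dirichlet((10.0, 6.0, 4.0))
        sub = rng.integers(0, 2**31 - 1, size=2)
        stepwise = make_stepwise_dvh(
            StepwisePlanSpec(
                shell_doses=(outer, intermediate, inner),
                shell_fractions=tuple(fracs),
                transition_width=transition_width,
                noise_sd=noise_sd,
                seed=int(sub[0]),
            )
        )
        uniform = make_uniform_dvh(
            outer, conventional_heterogeneity_sd, seed=int(sub[1])
        )
        gradient = Regimen(
            phases=((stepwise, 1), (uniform, k)),
            description=f"synthetic case {i + 1}: 1 gradient + {k} uniform",
        )
        conventional = Regimen(
            phases=((uniform, k + 1),),
            description=f"synthetic case {i + 1}: {k + 1} uniform",
        )
        cases.append(
            SyntheticCase(
                gradient=gradient,
                conventional=conventional,
                meta={
                    "case": i + 1,
                    "n_conventional": k,
                    "outer_dose_gy": outer,
                    "intermediate_dose_gy": intermediate,
                    "inner_dose_gy": inner,
                    "shell_fractions": tuple(float(f) for f in fracs),
                },
            )
        )
    return cases
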