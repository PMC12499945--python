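"""Regimen comparison reports with Monte Carlo uncertainties.

Builds the quantities a treatment comparison prints — per-phase EUD,
per-fraction EQD2, course totals, and the percent differences between a
gradient regimen and its conventional comparator — each as mean +/- SD
(k=1) over a common set of LQ-parameter draws. Differences are evaluated
per draw, so parameter uncertainty common to both regimens cancels where
it should.

The Monte Carlo here is vectorized over draws (the generic scalar path is
:func:`stepgrad.montecarlo.propagate`); both produce identical draws for
the same seed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from stepgrad.dvh import DVH
from stepgrad.lq import LQParams
from stepgrad.montecarlo import MCConfig, MCEstimate, _sample_parameter_arrays, _sample_sd
from stepgrad.regimen import Regimen, analyze_regimen


def _eud_draws(dvh: DVH, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """EUD of one DVH for every (alpha, beta) draw, vectorized."""
    d = dvh.bin_dose
    nu = dvh.bin_fraction
    mask = nu > 0
    d, nu = d[mask], nu[mask]
    if d.size == 1:  # uniform phase: EUD is the dose, independent of draws
        return np.full(alpha.shape, float(d[0]))
    log_terms = (
        np.log(nu)[None, :]
        - alpha[:, None] * d[None, :]
        - beta[:, None] * d[None, :] ** 2
    )
    L = -logsumexp(log_terms, axis=1)
    L = np.clip(L, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        quad = (-alpha + np.sqrt(alpha * alpha + 4.0 * beta * L)) / (2.0 * beta)
    return np.where(beta > 0, quad, L / alpha)


def _eqd2_fr_draws(eud: np.ndarray, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    ab = alpha / beta
    return eud * (eud + ab) / (2.0 + ab)


def _estimate(values: np.ndarray) -> MCEstimate:
    return MCEstimate(
        mean=float(values.mean()),
        sd=_sample_sd(values),
        n_effective=int(values.size),
    )


def regimen_mc_report(
    test: Regimen,
    reference: Regimen,
    params: LQParams = LQParams(),
    mc: MCConfig | None = None,
) -> dict:
    """Point estimates and MC uncertainties for a regimen comparison.

    Returns a dict with ``point`` (the deterministic comparison at the base
    parameters) and, under ``mc``, an :class:`MCEstimate` for every
    reported quantity, all evaluated on one common stream of parameter
    draws.
    """
    if mc is None:
        mc = MCConfig()
    rng = np.random.default_rng(mc.seed)
    alpha, beta = _sample_parameter_arrays(params, mc, rng)

    def regimen_draws(reg: Regimen) -> dict:
        phases = []
        total = np.zeros_like(alpha)
        for dvh, count in reg.phases:
            e = _eud_draws(dvh, alpha, beta)
            q = _eqd2_fr_draws(e, alpha, beta)
            phases.append({"eud": e, "eqd2_per_fraction": q, "fraction_count": count})
            total = total + count * q
        return {"phases": phases, "total": total, "first_fraction": phases[0]["eqd2_per_fraction"]}

    t = regimen_draws(test)
    r = regimen_draws(reference)
    delta_fr = 100.0 * (t["first_fraction"] - r["first_fraction"]) / r["first_fraction"]
    delta_total = 100.0 * (t["total"] - r["total"]) / r["total"]

    point_test = analyze_regimen(test, params)
    point_ref = analyze_regimen(reference, params)
    return {
        "params": params,
        "mc_config": mc,
        "point": {
            "test": point_test,
            "reference": point_ref,
            "delta_first_fraction": 100.0
            * (point_test.first_fraction_eqd2 - point_ref.first_fraction_eqd2)
            / point_ref.first_fraction_eqd2,
            "delta_total": 100.0
            * (point_test.total_eqd2 - point_ref.total_eqd2)
            / point_ref.total_eqd2,
        },
        "mc": {
            "test_phases": [
                {
                    "eud": _estimate(p["eud"]),
                    "eqd2_per_fraction": _estimate(p["eqd2_per_fraction"]),
                    "fraction_count": p["fraction_count"],
                }
                for p in t["phases"]
            ],
            "reference_phases": [
                {
                    "eud": _estimate(p["eud"]),
                    "eqd2_per_fraction": _estimate(p["eqd2_per_fraction"]),
                    "fraction_count": p["fraction_count"],
                }
                for p in r["phases"]
            ],
            "test_first_fraction_eqd2": _estimate(t["first_fraction"]),
            "reference_first_fraction_eqd2": _estimate(r["first_fraction"]),
            "test_total_eqd2": _estimate(t["total"]),
            "reference_total_eqd2": _estimate(r["total"]),
            "delta_first_fraction": _estimate(delta_fr),
            "delta_total": _estimate(delta_total),
        },
    }


def format_report(report: dict) -> str:
    """Human-readable rendering of :func:`regimen_mc_report` output."""
    p = report["params"]
    mc = report["mc_config"]
    e = report["mc"]
    lines = [
        "Regimen comparison (EQD2 scale)",
        f"  LQ parameters: alpha={p.alpha} /Gy, beta={p.beta} /Gy^2, "
        f"alpha/beta={p.alpha_beta:g} Gy",
        f"  Monte Carlo: n={mc.n_samples}, cv={mc.cv}, mode={mc.mode}, seed={mc.seed}",
        "",
    ]
    for name, key in (("gradient (test)", "test_phases"), ("conventional (reference)", "reference_phases")):
        lines.append(f"  {name}:")
        for i, ph in enumerate(e[key], 1):
            lines.append(
                f"    phase {i}: {ph['fraction_count']} fx, "
                f"EUD {ph['eud']}, EQD2/fr {ph['eqd2_per_fraction']} Gy"
            )
    lines += [
        "",
        f"  first fraction EQD2: {e['test_first_fraction_eqd2']} vs "
        f"{e['reference_first_fraction_eqd2']} Gy",
        f"  course total EQD2:   {e['test_total_eqd2']} vs {e['reference_total_eqd2']} Gy",
        f"  delta first fraction: {e['delta_first_fraction']} %",
        f"  delta total course:   {e['delta_total']} %",
    ]
    return "\n".join(lines)


def report_row(report: dict) -> dict:
    """Flat machine-readable row (mean/sd pairs) for tabular output."""
    e = report["mc"]
    row = {}
    for key in (
        "test_first_fraction_eqd2",
        "reference_first_fraction_eqd2",
        "test_total_eqd2",
        "reference_total_eqd2",
        "delta_first_fraction",
        "delta_total",
    ):
        row[key] = e[key].mean
        row[f"{key}_sd"] = e[key].sd
    return row
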