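"""Published 29-case cohort: fixtures and recomputed summaries.

The package ships, as reviewable delimited text, the per-case results of a
29-patient cohort of bulky tumors treated with one stepwise-gradient
fraction followed by conventional uniform fractions:

* an EQD2 table — per-fraction and whole-course EQD2 for the gradient
  regimen and its conventional comparator, with k=1 uncertainties and the
  percent differences Delta_1fr and Delta_total;
* a clinical table — tumor site, initial volume, prescription doses per
  nested shell, response class and percent volume reduction.

Every derived quantity (the Delta columns, cohort mean/min/max, response
rates, medians) is *recomputed* here from the primary columns rather than
trusted. Because the published values are rounded to their last printed
digit, recomputed ratios can legitimately differ from the printed ones by
more than one unit in the last place; consistency checks therefore use
interval arithmetic over the printed rounding (each printed value ``x`` with
``k`` decimals stands for the interval ``x +/- 0.5 * 10**-k``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

_NUMERIC_EQD2 = [
    "eqd2_sg_fr", "u_sg_fr", "eqd2_c_fr", "u_c_fr", "delta_fr", "u_delta_fr",
    "eqd2_sg_total", "u_sg_total", "eqd2_c_total", "u_c_total",
    "delta_total", "u_delta_total",
]


@dataclass(frozen=True)
class CaseRecord:
    """One cohort case, merging the EQD2 and clinical tables."""

    case_id: int
    n_conventional: int
    has_third_phase: bool
    eqd2_sg_fr: float
    eqd2_c_fr: float
    eqd2_sg_total: float
    eqd2_c_total: float
    initial_gtv_cc: float
    outer_dose_gy: float
    intermediate_dose_gy: float | None
    inner_dose_gy: float | None
    response_class: str  # complete | partial | stable | not_assessable
    pct_volume_reduction: float | None


def _data_text(name: str) -> str:
    return (resources.files("stepgrad") / "data" / name).read_text()


def half_ulp(printed: str) -> float:
    """Half a unit in the last printed decimal place of a numeral string."""
    printed = printed.strip()
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return 0.5 * 10.0 ** (-decimals)


def eqd2_table() -> pd.DataFrame:
    """EQD2 table as printed, one row per case.

    Numeric columns are parsed to float; for each primary value column a
    companion ``<col>_hulp`` column holds half its printed rounding step, so
    downstream checks can reason about transcription precision.
    """
    rows = list(csv.DictReader(_data_text("cohort_eqd2.tsv").splitlines(), delimiter="\t"))
    df = pd.DataFrame(rows)
    hulps = {
        f"{c}_hulp": df[c].map(half_ulp)
        for c in _NUMERIC_EQD2
        if not c.startswith("u_")
    }
    for c in _NUMERIC_EQD2:
        df[c] = df[c].astype(float)
    df["case"] = df["case"].astype(int)
    df["n_conventional"] = df["n_conventional"].astype(int)
    df["third_phase"] = df["third_phase"].astype(int).astype(bool)
    return pd.concat([df, pd.DataFrame(hulps, index=df.index)], axis=1)


def clinical_table() -> pd.DataFrame:
    """Clinical table, one row per case; 'NA' entries become NaN."""
    from io import StringIO

    df = pd.read_csv(
        StringIO(_data_text("cohort_clinical.tsv")),
        sep="\t",
        na_values=["NA"],
        keep_default_na=False,
    )
    return df


_RESPONSE_NAMES = {
    "C": "complete",
    "P": "partial",
    "S": "stable",
}


def load_case_records() -> list[CaseRecord]:
    """Merge the two tables into typed per-case records."""
    eq = eqd2_table().set_index("case")
    cl = clinical_table().set_index("case")
    records = []
    for case in eq.index:
        e, c = eq.loc[case], cl.loc[case]
        resp = c["radiologic_response"]
        records.append(
            CaseRecord(
                case_id=int(case),
                n_conventional=int(e["n_conventional"]),
                has_third_phase=bool(e["third_phase"]),
                eqd2_sg_fr=float(e["eqd2_sg_fr"]),
                eqd2_c_fr=float(e["eqd2_c_fr"]),
                eqd2_sg_total=float(e["eqd2_sg_total"]),
                eqd2_c_total=float(e["eqd2_c_total"]),
                initial_gtv_cc=float(c["initial_gtv_cc"]),
                outer_dose_gy=float(c["outer_dose_gy"]),
                intermediate_dose_gy=None
                if pd.isna(c["intermediate_dose_gy"])
                else float(c["intermediate_dose_gy"]),
                inner_dose_gy=None
                if pd.isna(c["inner_dose_gy"])
                else float(c["inner_dose_gy"]),
                response_class=_RESPONSE_NAMES.get(resp, "not_assessable"),
                pct_volume_reduction=None
                if pd.isna(c["pct_volume_reduction"])
                else float(c["pct_volume_reduction"]),
            )
        )
    return records


def relative_difference(a: float, b: float) -> float:
    """Percent excess of ``a`` over ``b``: ``100 * (a - b) / b``."""
    if b <= 0:
        raise ValueError(f"reference value must be > 0, got {b}")
    return 100.0 * (a - b) / b


def recompute_deltas(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute Delta_1fr and Delta_total from the printed EQD2 columns.

    Adds ``delta_fr_recomputed`` / ``delta_total_recomputed`` plus, for each,
    the interval ``[*_lo, *_hi]`` that the printed rounding of the inputs
    allows, and a boolean ``*_consistent`` flag: the printed Delta (widened
    by half its own ULP) must overlap that interval.
    """
    if df is None:
        df = eqd2_table()
    df = df.copy()
    for tag, a_col, b_col in [
        ("delta_fr", "eqd2_sg_fr", "eqd2_c_fr"),
        ("delta_total", "eqd2_sg_total", "eqd2_c_total"),
    ]:
        a, b = df[a_col], df[b_col]
        ha, hb = df[f"{a_col}_hulp"], df[f"{b_col}_hulp"]
        df[f"{tag}_recomputed"] = 100.0 * (a - b) / b
        lo = 100.0 * ((a - ha) / (b + hb) - 1.0)
        hi = 100.0 * ((a + ha) / (b - hb) - 1.0)
        df[f"{tag}_lo"], df[f"{tag}_hi"] = lo, hi
        hp = df[f"{tag}_hulp"]
        df[f"{tag}_consistent"] = (df[tag] + hp >= lo) & (df[tag] - hp <= hi)
    return df


def cohort_delta_summary(df: pd.DataFrame | None = None) -> dict:
    """Mean/min/max of the recomputed per-case percent differences.

    Also reports ``tol_*``: how far each recomputed summary can sit from the
    corresponding summary of the unrounded source values, given the printed
    rounding of the inputs (mean of the per-case interval half-widths for
    the mean; the per-case half-width at the extremes for min/max).
    """
    df = recompute_deltas(df)
    out = {}
    for tag in ("delta_fr", "delta_total"):
        r = df[f"{tag}_recomputed"]
        half = 0.5 * (df[f"{tag}_hi"] - df[f"{tag}_lo"])
        out[tag] = {
            "mean": float(r.mean()),
            "min": float(r.min()),
            "max": float(r.max()),
            "tol_mean": float(half.mean()),
            "tol_min": float(half[r.idxmin()]),
            "tol_max": float(half[r.idxmax()]),
        }
    return out


def outcome_summary(df: pd.DataFrame | None = None) -> dict:
    """Clinical outcome summaries recomputed from the clinical table.

    Response percentages use all cases as denominator; the median volume
    reduction uses assessable cases only. Medians over an even count are the
    midpoint of the two central values.
    """
    if df is None:
        df = clinical_table()
    n = len(df)
    resp = df["radiologic_response"].map(lambda r: _RESPONSE_NAMES.get(r, "not_assessable"))
    counts = {
        name: int((resp == name).sum())
        for name in ("complete", "partial", "stable", "not_assessable")
    }
    reduction = df["pct_volume_reduction"].dropna().astype(float)
    return {
        "n_cases": n,
        "response_counts": counts,
        "response_pct": {k: 100.0 * v / n for k, v in counts.items()},
        "n_assessable": int(reduction.size),
        "median_volume_reduction_pct": float(np.median(reduction)),
        "median_initial_gtv_cc": float(df["initial_gtv_cc"].median()),
        "median_outer_dose_gy": float(df["outer_dose_gy"].median()),
        "median_intermediate_dose_gy": float(df["intermediate_dose_gy"].median()),
        "median_inner_dose_gy": float(df["inner_dose_gy"].median()),
    }


def verify_consistency(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check EQD2 additivity of the printed columns, case by case.

    For a schedule of one gradient fraction plus ``k`` conventional
    fractions the totals must satisfy

        total_sg = sg_fr + k * c_fr        (two-phase identity)
        total_c  = (k + 1) * c_fr

    up to printed rounding. The tolerance per row propagates half a ULP of
    every printed figure through the arithmetic. Cases with a third treatment
    phase are exempt from the two-phase identity (their gradient total
    includes a phase whose per-fraction EQD2 is not a printed column) but
    still checked on the conventional side.
    """
    if df is None:
        df = eqd2_table()
    df = df.copy()
    k = df["n_conventional"]
    df["residual_sg_gy"] = (
        df["eqd2_sg_total"] - (df["eqd2_sg_fr"] + k * df["eqd2_c_fr"])
    ).abs()
    df["tol_sg_gy"] = (
        df["eqd2_sg_total_hulp"] + df["eqd2_sg_fr_hulp"] + k * df["eqd2_c_fr_hulp"]
    )
    df["residual_c_gy"] = (df["eqd2_c_total"] - (k + 1) * df["eqd2_c_fr"]).abs()
    df["tol_c_gy"] = df["eqd2_c_total_hulp"] + (k + 1) * df["eqd2_c_fr_hulp"]
    df["flag_sg"] = (df["residual_sg_gy"] > df["tol_sg_gy"]) & ~df["third_phase"]
    df["flag_c"] = df["residual_c_gy"] > df["tol_c_gy"]
    return df
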