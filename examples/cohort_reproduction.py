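"""Recompute every derived quantity of the packaged 29-case cohort.

The package ships the per-case EQD2 and clinical tables of a 29-patient
stepwise-gradient cohort as delimited text. This script recomputes the
percent differences between regimens, their cohort summaries, the clinical
outcome summaries, and the EQD2 additivity consistency checks.
"""

from stepgrad import cohort_delta_summary, outcome_summary, verify_consistency

deltas = cohort_delta_summary()
s = deltas["delta_fr"]
print(f"first-fraction EQD2 excess: mean {s['mean']:.1f}%  (min {s['min']:.1f}, max {s['max']:.1f})")
s = deltas["delta_total"]
print(f"full-course EQD2 excess:    mean {s['mean']:.2f}%  (min {s['min']:.2f}, max {s['max']:.2f})")

o = outcome_summary()
rc, rp = o["response_counts"], o["response_pct"]
print(
    f"radiologic response: complete {rc['complete']}/{o['n_cases']} ({rp['complete']:.1f}%), "
    f"partial {rc['partial']}/{o['n_cases']} ({rp['partial']:.1f}%)"
)
print(
    f"median volume reduction {o['median_volume_reduction_pct']:.0f}% "
    f"({o['n_assessable']} assessable); median initial GTV {o['median_initial_gtv_cc']:.0f} cc"
)

c = verify_consistency()
print(
    f"additivity: max residual {max(c['residual_sg_gy'].max(), c['residual_c_gy'].max()):.2f} Gy, "
    f"{int(c['flag_sg'].sum() + c['flag_c'].sum())} rows beyond printed rounding"
)
print()
print(
    "A single gradient fraction delivers on average about twice the EQD2 of\n"
    "a conventional fraction, while the complete courses differ by only a\n"
    "few percent — the premise for attributing observed responses to the\n"
    "heterogeneous first fraction rather than total dose escalation."
)
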