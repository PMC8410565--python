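"""Cohort-level analytics on a simulated multi-group study.

Simulates per-subject CTC counts for cancer groups, benign controls and
healthy donors (calibrated zero-inflated negative binomials), then runs
the reporting battery: per-group positivity, count-threshold diagnostics
with ROC, and Kaplan–Meier recurrence analysis by CTC status.
"""

from rarecell.reporting import (
    cohort_report,
    km_recurrence,
    positivity_rate,
    roc_auc_counts,
)
from rarecell.simulate import simulate_cohort

cohort = simulate_cohort(n_per_group=150, seed=7)

for group in ("HCC", "BC", "CHB/LC", "HD"):
    pct, n_pos, n = positivity_rate(cohort, group)
    counts = cohort.loc[cohort["group"] == group, "ctc_count"]
    print(f"{group:7s} positivity {pct:5.1f}% ({n_pos}/{n}), "
          f"mean {counts.mean():.2f} ± {counts.std():.2f}")

cases = cohort.loc[~cohort["group"].isin(["HD", "CHB/LC", "BHL"]), "ctc_count"]
controls = cohort.loc[cohort["group"] == "HD", "ctc_count"]
auc, ci = roc_auc_counts(cases, controls)
print(f"cancer-vs-healthy ROC AUC = {auc:.3f} (95% CI {ci[0]:.3f}-{ci[1]:.3f})")

hcc = cohort[cohort["group"] == "HCC"]
km = km_recurrence(hcc)
print(f"median time to recurrence: {km.medians}  "
      f"(log-rank p = {km.logrank_p:.2g})")
report = cohort_report(cohort)
print(f"report sections: {sorted(report)}")
# Positivity in cancer groups sits near 60% against <1% in healthy blood,
# and count-positive subjects recur earlier — the prognostic contrast the
# KM analysis quantifies.
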