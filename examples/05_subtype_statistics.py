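"""Mutual-exclusivity and cohort statistics for fusion subtypes.

A 2x2 table of SKIL-positive vs ETS-positive samples is tested with the
exact-enumeration two-sided Fisher test; cohort frequencies reproduce the
printed percentages; the t-test and first-order error propagation back the
assay-comparison figures.
"""

from oncopipe.subtype_stats import (ExclusivityTable, cohort_frequency,
                                    fisher_exact_two_sided, propagate_sem_ratio,
                                    ttest_unpaired_two_tailed)

# rows: SKIL+ / SKIL-, columns: ETS+ / ETS- — a 41-sample cohort style table
table = ExclusivityTable(a=1, b=6, c=21, d=13)
p = fisher_exact_two_sided(table)
print(f"SKIL+ samples that are ETS-: {table.b}/{table.a + table.b}; "
      f"Fisher two-sided p = {p:.3f}")
print(f"  (p < 0.05 suggests SKIL and ETS alterations are mutually exclusive)")

print(f"cohort frequency 6/540  -> {cohort_frequency(6, 540)}%")
print(f"cohort frequency 1/27   -> {cohort_frequency(1, 27)}%")

control = [1.00, 1.10, 0.95]
treated = [1.85, 2.10, 1.95]
t = ttest_unpaired_two_tailed(control, treated)
print(f"unpaired two-tailed t-test: t={t.t:.2f}, df={t.df:.0f}, p={t.p:.4f}")

ratio = propagate_sem_ratio(num_mean=2.0, num_sem=0.15, den_mean=1.0, den_sem=0.08)
print(f"normalized assay ratio: {ratio.mean:.2f} +/- {ratio.sem:.3f} (s.e.m., "
      f"first-order propagation)")
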