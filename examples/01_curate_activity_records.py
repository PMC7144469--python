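"""Curate raw activity records into per-compound regression labels.

Builds a miniature ChEMBL-export-like table mixing parameter forms and
units, runs the strict curation protocol, and prints the per-compound
aggregates.  The point: heterogeneous raw rows (Ki in µM, IC50 in nM, pKi)
all standardize onto one scale — log10 of Ki in nM — before aggregation.
"""

from uqscreen.data_prep import ActivityRecord, curate

records = [
    # three measurements of the same compound in three different forms
    ActivityRecord("R0", "CPD_A", "TGT", "Ki", "=", 0.1, "µM"),      # 100 nM
    ActivityRecord("R1", "CPD_A", "TGT", "IC50", "=", 200.0, "nM"),  # Ki = 100 nM
    ActivityRecord("R2", "CPD_A", "TGT", "pKi", "=", 7.0, None),     # 100 nM
    # a single very potent compound
    ActivityRecord("R3", "CPD_B", "TGT", "Ki", "=", 0.2, "nM"),
    # dropped by the strict protocol: inequality relation
    ActivityRecord("R4", "CPD_C", "TGT", "Ki", "<", 50.0, "nM"),
]

curated, report = curate(records, relation_mode="strict")

print("filtering cascade:")
for stage, n_in, n_out in report.stages:
    print(f"  {stage:18s} {n_in:2d} -> {n_out:2d}")

print("\nper-compound aggregates (label = mean log10 Ki[nM]):")
for c in curated:
    print(
        f"  {c.compound_id}: n={c.n_values}  label={c.label:.4f}  "
        f"std={c.std_log_activity:.4f}  mean_Ki={c.mean_activity_nm:.1f} nM"
    )

# CPD_A's three forms all standardize to log10(100) = 2, so its std is 0.
# CPD_B has one value: its std is exactly 0 by the population convention.
# CPD_C never reaches aggregation: '<' is not an equality relation.
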