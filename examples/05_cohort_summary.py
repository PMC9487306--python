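"""Summary statistics of the bundled 20-case cohort characteristics table.

Each row lists a case's lesion count, lesion volumes, total target volume
and the largest per-axis spread between lesions (R_max). The summary
reports medians and ranges, the form in which multi-metastasis SRS cohorts
are usually characterized.
"""

from sacao import cohort_summary, table1_fixture

table = table1_fixture()
print(table[["case_id", "n_lesions", "total_volume", "r_max_x", "r_max_y", "r_max_z"]]
      .to_string(index=False))
print()
print("median (min-max) per characteristic:")
summary = cohort_summary(table)
for name, row in summary.iterrows():
    unit = "cc" if name == "total_volume" else "cm"
    print(f"  {name}: {row['median']} ({row['min']}-{row['max']}) {unit}")
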