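"""Reproduce the cohort bookkeeping on the deterministic metadata fixture:
the mixture-eligibility filter arithmetic and the n (%) summary table.

The fixture has 9,515 subjects with the pooled cohort's published margins;
the filter removes antibiotic users/unknowns and low/zero genus counts,
leaving 5,329 subjects for the fit, and the summary reports percentages
among subjects with known values (79% controls overall, 88% in the adult
no-antibiotic stratum).
"""

from bifidopart import dmm_eligibility_filter, summarize_metadata
from bifidopart.synthetic import generate_table1_fixture

md = generate_table1_fixture()
report = dmm_eligibility_filter(md, md.set_index("sample_id")["bif_total"])
print(f"input subjects:      {len(md)}")
print(f"excluded:            {report.excluded}")
print(f"zero-count (no_Bif): {len(report.zero_bif)}")
print(f"retained for fit:    {len(report.retained)}")

summary = summarize_metadata(md, ["condition"])
row = summary[(summary.stratum == "all") & (summary.level == "control")].iloc[0]
print(f"controls overall:    {row['n']} ({row['display']})")

mask = (md["age_category"] == "adult") & (md["antibiotic_use"] == "no")
summary2 = summarize_metadata(md, ["condition"], strata={"adult_no_ab": mask})
row2 = summary2[(summary2.stratum == "adult_no_ab") & (summary2.level == "control")].iloc[0]
print(f"controls, adult no-antibiotic stratum: {row2['n']} ({row2['display']})")
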