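"""Generate a synthetic paired study and run the QC funnel on the discovery cohort.

The generator plants 36 deleterious variants in 25 panel genes (aggregate
carrier prevalence ~29%) on top of ~40 rare benign/VUS variants per patient,
then the five-criterion QC cascade (MAF < 0.01, exonic, depth > 20, strand
bias, VAF >= 25%) and the 1,166-gene panel intersection are applied.
"""

from germlinekit import pipeline, synthetic

study = synthetic.generate_study(seed=1, outdir=None)
reference = synthetic.reference_table_from_frame(
    study["reference"], study["discovery"].config.reference_an)
cohort = study["discovery"]
result = pipeline.run_cohort(cohort.variants, cohort.roster, study["panel"], reference)

print("QC funnel (variants surviving each stage):")
for stage, count in result.filter_report.funnel():
    print(f"  {stage:12s} {count}")

report = result.report
print(f"\ndeleterious variants: {report.n_deleterious_variants}")
print(f"carriers: {report.n_carriers}/{report.n_patients} "
      f"({report.carrier_percent}%), {report.n_dual_carriers} with two variants")
print("\nEach funnel line counts variants passing that filter; the final line is")
print("the in-panel set that enters ACMG classification.")
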