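"""Classify variants with the ACMG/AMP evidence-combining rules.

Evidence codes (PVS1, PS1-4, PM1-6, PP1-5 pathogenic-direction; BA1, BS1-4,
BP1-7 benign-direction) combine into five tiers, which triage into the three
bins used for cohort reporting: deleterious (Pathogenic + Likely pathogenic),
VUS, and benign (Benign + Likely benign).
"""

from germlinekit import acmg

examples = [
    ("stop-gain in a loss-of-function gene, absent from controls", ("PVS1", "PM2")),
    ("two strong lines of pathogenic evidence", ("PS1", "PS2")),
    ("rare missense with nothing else known", ("PM2",)),
    ("common in East Asians (>5%)", ("BA1",)),
    ("contradictory: LoF but common", ("PVS1", "BA1")),
]

for label, codes in examples:
    cls = acmg.classify(codes)
    print(f"{','.join(codes):12s} -> {cls.tier5:17s} ({cls.tier3})   # {label}")

print("\nContradictory pathogenic and benign evidence resolves to VUS, the")
print("conservative reading of the guideline's conflict clause.")
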