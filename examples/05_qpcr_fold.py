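"""Fold enrichment of 5-hmC pulldown qPCR over a control.

Given input and pulldown Ct values per locus, enrichment relative to a
control is 2^(Input - Pulldown)_sample / 2^(Input - Pulldown)_control:
each cycle of earlier pulldown amplification doubles the inferred
amount of captured 5-hmC DNA.
"""

from helpgt.expression import QpcrMeasurement, qpcr_fold_enrichment

control = QpcrMeasurement("normal_control", input_ct=21.0, pulldown_ct=19.5)
loci = [
    QpcrMeasurement("GATA6_promoter_cancer", input_ct=20.5, pulldown_ct=16.5),
    QpcrMeasurement("unchanged_locus", input_ct=22.0, pulldown_ct=20.5),
    QpcrMeasurement("depleted_locus", input_ct=21.0, pulldown_ct=20.8),
]

print(f"control delta-Ct = {control.input_ct - control.pulldown_ct:.1f}")
for locus in loci:
    fold = qpcr_fold_enrichment(locus, control)
    print(f"{locus.locus}: delta-Ct = {locus.input_ct - locus.pulldown_ct:.1f}, "
          f"fold enrichment = {fold:.2f}")
print("(fold > 1: more 5-hmC captured than in the control)")
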