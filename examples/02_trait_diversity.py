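"""Profile trait diversity: means, coefficients of variation, normality.

The CV (100 x SD/mean) is the standard diversity measure for germplasm
panels; traits with CV > 10% are considered highly variable and useful
for selection.
"""

import germeval as ge

table, _ = ge.generate(ge.default_config(seed=7))
summary = ge.summarize_table(table)

cvs = {s.trait_code: s.cv_percent for s in summary}
high = [c for c, v in cvs.items() if v > 10]
print(f"protein: mean {summary['protein'].mean:.2f}%, CV {cvs['protein']:.2f}%")
print(f"oil:     mean {summary['oil'].mean:.2f}%, CV {cvs['oil']:.2f}%")
print(f"CV range across 34 traits: {min(cvs.values()):.2f}% - {max(cvs.values()):.2f}%")
print(f"{len(high)} traits exceed CV 10%: {', '.join(high)}")
print(f"protein + oil account for {summary.aggregates['protein_plus_oil']:.2f}% "
      "of kernel dry weight on average")
print(f"unsaturated fatty acids sum to {summary.aggregates['ufa_sum']:.2f}% "
      "of total fatty acids")
non_normal = [s.trait_code for s in summary if s.normality_p is not None
              and s.normality_p < 0.05]
print(f"Shapiro-Wilk flags {len(non_normal)} trait(s) at alpha=0.05 "
      "(advisory only)")
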