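"""Map correlations between seed nutrition and fiber traits.

The protein-oil trade-off is the panel's strongest signal; the
cross-family report ranks nutrition x fiber links that matter for
coordinated breeding.
"""

import germeval as ge

table, _ = ge.generate(ge.default_config(seed=7))
corr = ge.pearson_matrix(table)

r, p, stars = corr.pair("protein", "oil")
print(f"protein vs oil: r = {r:.3f}{stars} (p = {p:.2g}) - the classic "
      "storage trade-off")

print("\nstrongest protein x fiber-yield correlations:")
for (a, b), r, stars in ge.cross_block_report(corr, table, "protein", "fiber_yield"):
    print(f"  {a} - {b}: r = {r:+.3f}{stars}")

print("\nstrongest oil x fiber-yield correlations:")
for (a, b), r, stars in ge.cross_block_report(corr, table, "oil", "fiber_yield"):
    print(f"  {a} - {b}: r = {r:+.3f}{stars}")
print("** marks p < 0.01, * marks p < 0.05 (uncorrected).")
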