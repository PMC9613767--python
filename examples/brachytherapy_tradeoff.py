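"""Continuous radiation of a slowly invading tumor: kill vs spread.

Integrates the slow treatment system with prostate-like parameters
(d = 8.64e-4 mm^2/day, alpha = 0.012/day, radiosensitivities 0.15/Gy and
0.048/Gy^2) under a decaying radiation source implanted on day 20, and
reports the stem-cell burden and invaded width on day 80 for an
untreated tumor, a moderate dose rate and an extreme dose rate.
"""

from stemwave.experiments import brachytherapy_comparison

rows = brachytherapy_comparison(r0_values=(5.71, 50.0), delta=0.3,
                                t_end=80.0)
print(f"{'R0 (Gy/day)':>12} {'CSC burden (mm)':>16} {'width (mm)':>11} "
      f"{'peak u':>8}")
for r in rows:
    print(f"{r['R0']:>12} {r['burden']:>16.4f} {r['width']:>11.3f} "
          f"{r['peak']:>8.4f}")

print(
    "\nThe moderate dose rate shows the treatment trade-off: the non-stem"
    "\ncompartment is suppressed, which releases the stem cells - a LARGER"
    "\nstem-cell burden spread over a WIDER region than without treatment."
    "\nThe extreme dose rate also kills stem cells outright (via delta*T)"
    "\nand nearly eradicates the tumor before it regrows from the dose's"
    "\ndecaying tail."
)
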