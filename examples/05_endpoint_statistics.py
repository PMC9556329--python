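"""Trial endpoint statistics on their published worked-example inputs.

Every number here is recomputed from the printed counts and statistics of
the neoadjuvant trial this package models.
"""

from immunopred.endpoints import (compute_tmb, design_power, fisher_exact,
                                  km_estimate, response_rate_ci,
                                  welch_p_from_stats)

r = response_rate_ci(29, 143)
print(f"MPR rate: {r.rate_percent}% (29 of 143; "
      f"95% CI {r.ci_percent[0]}-{r.ci_percent[1]}%, Clopper-Pearson)")
r = response_rate_ci(8, 143)
print(f"pCR rate: {r.rate_percent}% (8 of 143; "
      f"95% CI {r.ci_percent[0]}-{r.ci_percent[1]}%)")

p = fisher_exact([[6, 47], [1, 19], [15, 30]])
print(f"\nMPR by PD-L1 TPS group (<1% / 1-49% / >=50%): "
      f"Freeman-Halton P = {p:.2f}")
for pair, table in [("<10 vs 10-15", [[8, 52], [1, 9]]),
                    ("<10 vs >=16", [[8, 52], [5, 10]]),
                    ("10-15 vs >=16", [[1, 9], [5, 10]])]:
    print(f"MPR by TMB {pair} mut/Mb: Fisher P = {fisher_exact(table):.2f}")

print("\npredicted-probability comparisons, two-sided p from (t, df):")
for label, t, df in [("MPR vs non-MPR", -5.47, 27.02),
                     ("MPR vs PD", -3.18, 28.45),
                     ("non-MPR vs PD", -1.77, 9.52)]:
    print(f"  {label}: p = {welch_p_from_stats(t, df):.2g}")

power, critical = design_power(0.05, 0.15, 0.05, 180)
print(f"\ndesign: n=180, null 5% vs alternative 15%, one-sided alpha 0.05")
print(f"  exact binomial power {power:.4f} (critical value: "
      f"{critical} responders)")

rec = compute_tmb(5, 2_500_000)
print(f"\nTMB example: 5 protein-affecting mutations / 2.5 Mb covered "
      f"= {rec.tmb:.1f} mut/Mb (stratum {rec.tmb_group})")

curve = km_estimate([1, 2, 3, 4, 5], [1, 0, 1, 1, 0])
print(f"Kaplan-Meier on (1, 2+, 3, 4, 5+): S = "
      f"{', '.join(f'{s:.3f}' for s in curve.survival)} at t = "
      f"{', '.join(str(int(t)) for t in curve.times)}")
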