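"""Build and filter the marker-combination feature space.

Shows the narrowing sequence the analysis uses: observed phenotypes ->
impossible-combination exclusion -> 50% detection filter -> 85% prevalence
split.
"""

from immunopred import CohortProfile, EffectSpec, default_panel
from immunopred.features import (apply_exclusion_rules, filter_by_detection,
                                 observed_phenotypes, split_by_prevalence)
from immunopred.simulate import generate_cohort, generate_immunome

panel = default_panel(5)
cohort = generate_cohort(CohortProfile(n_patients=100), seed=2)
pre, _ = generate_immunome(cohort, panel, EffectSpec.null(), seed=2,
                           n_populations=25)

observed = observed_phenotypes(pre)
possible = apply_exclusion_rules(observed, panel)
detected = filter_by_detection(pre.restrict(possible), 0.50)
split = split_by_prevalence(detected, 0.85)

print(f"combination universe (14 tubes x 2^5): {panel.n_universe}")
print(f"observed in >=1 sample:                {len(observed)}")
print(f"after CD3+/CD19+ exclusion rule:       {len(possible)}")
print(f"detected in >=50% of samples:          {len(detected.feature_ids)}")
print(f"  prevalent (>=85% detection):         {len(split.prevalent)}")
print(f"  non-prevalent:                       {len(split.non_prevalent)}")
print("each step only removes features; the prevalence split partitions")
print("the survivors into the two strata the model filters separately")
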