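"""Compare treatment groups against a stimulated control with Dunnett's test.

Simulates normalised ECM signals for a stimulated control and three
treatments, runs one-way ANOVA, and then Dunnett's many-to-one post hoc,
which controls the family-wise error rate across the three comparisons.
"""

import numpy as np

from ecmscreen import GroupData, dunnett, one_way_anova

rng = np.random.default_rng(0)
groups = [
    GroupData("TGFB1", rng.normal(1.00, 0.08, 6), is_control=True),
    GroupData("TGFB1+antibody", rng.normal(0.55, 0.08, 6)),
    GroupData("TGFB1+nintedanib", rng.normal(0.70, 0.08, 6)),
    GroupData("TGFB1+isotype", rng.normal(0.98, 0.08, 6)),
]

anova = one_way_anova(groups)
print(f"one-way ANOVA: F({anova.df_between},{anova.df_within}) = {anova.F:.2f}, p = {anova.p:.2e}")

result = dunnett(groups, control="TGFB1", seed=1)
print(result.round({"estimate": 3, "t": 2, "p_raw": 6, "p_adjusted": 6}).to_string(index=False))
# p_adjusted accounts for testing three treatments against one control;
# the isotype comparison should stay non-significant.
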