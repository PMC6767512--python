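"""Panel regressions of infestation intensity on climate and fire hazards.

A balanced 19-object x 8-year panel with known coefficients is fitted by
pooled OLS, fixed effects (within) and random effects (Swamy-Arora GLS);
the Chow test asks whether object intercepts are needed at all, the
Hausman test whether random effects are consistent.
"""

import geodefol as gd
from geodefol.panel import summarize_fits

_, panel, beta_true = gd.generate_climate_panel(gd.PanelSpec(seed=1))
po = gd.fit_pooled(panel)
fe = gd.fit_fixed_effects(panel)
re = gd.fit_random_effects(panel)

print("true coefficients:", dict(zip(re.beta.index, beta_true)))
print(summarize_fits([po, fe, re], "infestation").to_string())

ch = gd.chow_test(po, fe, panel)
ha = gd.hausman_test(fe, re)
print(f"\nChow    X2={ch.statistic:6.2f}  df={ch.df}  p={ch.p_value:.3f}")
print(f"Hausman X2={ha.statistic:6.2f}  df={ha.df}  p={ha.p_value:.3f}")
# A small Chow p-value says object intercepts matter (use FE/RE); a
# large Hausman p-value says RE is consistent with FE, so the more
# efficient random-effects estimates are preferred.
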