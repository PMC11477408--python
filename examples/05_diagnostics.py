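"""Evaluate sIgE analytes against oral-food-challenge outcomes.

Simulates a challenged cohort and reports single-analyte ROC AUCs plus
AIC best-subset logistic panels with and without the challenged fish's
own extract.
"""

from allergoscope import panel_evaluation, sensitization_filter
from allergoscope.simulate import generate_cohort

cohort, _ = generate_cohort(seed=4)
cohort = sensitization_filter(cohort)
report = panel_evaluation(cohort, "grass_carp", max_size=4)

print(f"grass carp challenge: {report.n_allergic}/{report.n_subjects} allergic")
print("top single analytes by AUC:")
print(report.single_auc.head(4).to_string(index=False))
print(f"\nreference: grass carp extract AUC = {report.target_auc:.3f}")
print("\nbest panels including the grass carp extract:")
print(report.with_target.to_frame().to_string(index=False))
print("\nbest panels excluding it:")
print(report.without_target.to_frame().to_string(index=False))
# The challenged fish's own extract ranks among the top single markers
# (with strongly correlated titres a sister-group analyte can edge it
# out in an arm this small); panels add some in-sample AUC, the pattern
# motivating component-resolved multi-allergen panels.
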