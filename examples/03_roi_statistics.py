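"""Speech-conditioned ROI analysis on a cohort with a listening gap.

Generates a cohort in which everyone looks at the face more while
listening (off-face weight 0.15) than while speaking (0.45), runs the
full pipeline (fixations -> face labels -> speech coding -> proportions)
and the 2 x 2 x 2 mixed ANOVA with nonparametric follow-up.
"""

from dyadgaze import (detect_fixations_table, label_fixations_table,
                      median_iqr_table, mixed_anova_2x2x2, roi_outcomes,
                      wilcoxon_signed_rank)
from dyadgaze.synthetic import (CohortSpec, default_profiles,
                                generate_cohort, with_off_face)

base = default_profiles()["western"]
profiles = {"speaking": with_off_face(base, 0.45),
            "listening": with_off_face(base, 0.15)}
spec = CohortSpec(n_per_group=8, session_duration_s=30.0, loss_rate=0.08,
                  seed=21)
cohort = generate_cohort(spec, profiles, profiles)

fixations, _ = detect_fixations_table(cohort.gaze)
labeled = label_fixations_table(fixations, cohort.face_boxes)
outcomes, _ = roi_outcomes(labeled, cohort.speech_events, cohort.gaze)
group_of = cohort.traits.set_index("participant")["group"]

print("median face fixation time (% of valid fixation time):")
print(median_iqr_table(outcomes, "face_prop", group_of).to_string(
    index=False, float_format=lambda v: f"{v:.1f}"))

anova = mixed_anova_2x2x2(outcomes, "face_prop", group_of)
print("\n2 (Group) x 2 (Speech) x 2 (Task) mixed ANOVA on face_prop:")
print(anova.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

wide = outcomes.pivot_table(index="participant", columns="speech_state",
                            values="face_prop")
res = wilcoxon_signed_rank(wide["listening"], wide["speaking"])
print(f"\nWilcoxon signed-rank (listening vs speaking): "
      f"Z = {res.z:.2f}, p = {res.p:.2g}, r = {res.r:.2f}")
print("\nThe Speech main effect dominates (listening > speaking face"
      "\nlooking), while Group effects stay at chance: both groups were"
      "\ngenerated from the same spatial profile here.")
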