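"""Gaze density maps and the cluster-based Monte Carlo permutation test.

Injects an extra mouth-located mixture component (weight 0.25) into
group B only, runs the full pipeline to per-participant smoothed density
maps on the normalized 11 x 14 degree face template, and tests the group
difference with the max-cluster-size permutation test.
"""

import numpy as np

from dyadgaze import (AnalysisConfig, build_density_maps,
                      detect_fixations_table, label_fixations_table,
                      roi_outcomes, run_permutation_analysis)
from dyadgaze.synthetic import (CohortSpec, InjectedEffect,
                                default_profiles, generate_cohort)

config = AnalysisConfig(n_permutations=1000)
effect = InjectedEffect(center_deg=(5.5, 9.8), weight=0.25)  # mouth
spec = CohortSpec(n_per_group=8, session_duration_s=30.0, loss_rate=0.08,
                  seed=33)
base = default_profiles()["eastern"]
cohort = generate_cohort(spec, base, base, injected_effect=effect,
                         config=config)

fixations, _ = detect_fixations_table(cohort.gaze, config)
labeled = label_fixations_table(fixations, cohort.face_boxes, config)
_, periods = roi_outcomes(labeled, cohort.speech_events, config=config)
maps = build_density_maps(labeled, cohort.face_boxes, periods, config)
print(f"density maps : {len(maps)} (participant x speech state, "
      "unit mass each)")

result = run_permutation_analysis(maps, cohort.group_of, "listening",
                                  config, rng=1)
print(f"t-threshold  : |t| > {result.t_crit:.2f} "
      f"(cluster-forming p = {config.cluster_forming_p}, df = {result.df})")
print(f"clusters     : {len(result.clusters)} "
      f"({len(result.significant_clusters)} significant at "
      f"alpha = {config.cluster_alpha})")
for c in result.clusters:
    row, col = np.asarray(c.pixels).mean(axis=0)
    print(f"  id {c.id}: sign {c.sign:8s} size {c.size:5d} px  "
          f"p = {c.p:.4f}  centroid ({col * 0.1:.1f}, {row * 0.1:.1f}) deg")
print(f"\ninjected effect sat at {effect.center_deg} deg (mouth); a"
      "\nsignificant cluster with its centroid there recovers it. The"
      "\nnegative-sign cluster is A-B < 0: group B gained mouth density.")
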