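"""Generate a small synthetic two-group cohort and look at its tables.

Builds 2 x 4 participants with group-specific face-scanning profiles
(mouth-heavy vs eye/center-heavy), two tasks each, and prints what the
generator produced: gaze sample counts, loss fraction, speech turns and
trait scores.
"""

from dyadgaze import AnalysisConfig
from dyadgaze.synthetic import CohortSpec, default_profiles, generate_cohort

profiles = default_profiles()
spec = CohortSpec(n_per_group=4, session_duration_s=30.0, loss_rate=0.08,
                  motion_amplitude_px=30.0, seed=9)
cohort = generate_cohort(spec, profiles["western"], profiles["eastern"],
                         config=AnalysisConfig())

n_sessions = cohort.gaze.groupby(["participant", "task"]).ngroups
print(f"participants : {len(cohort.participants)} "
      f"({spec.n_per_group} per group)")
print(f"sessions     : {n_sessions} (2 tasks each, "
      f"{spec.session_duration_s:.0f} s at 60 Hz)")
print(f"gaze samples : {len(cohort.gaze)}")
loss = 1.0 - cohort.gaze["valid"].mean()
print(f"invalid frac : {loss:.3f} (target loss_rate {spec.loss_rate})")
print(f"speech events: {len(cohort.speech_events)}")
print("\ntrait scores (AQ = autistic traits, LSAS = social anxiety):")
print(cohort.traits.to_string(index=False))
print("\nGroup B draws higher AQ/LSAS on average: the two groups use"
      "\ndistinct trait distributions, as in cross-cultural adult samples.")
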