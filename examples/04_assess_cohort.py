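"""Leave-one-subject-out assessment of a small labelled cohort.

Trains the trunk and hip models on every subject's peers, assesses each
trial and prints the outcome alongside the injected ground truth.
"""

from rehabmotion import generate_cohort
from rehabmotion.assessment import (
    AssessConfig, canonical_registry, classify_movement, loso_train,
)
from rehabmotion.features import assessment_preset, extract_features

cohort = generate_cohort(5, 6, fault_rate=0.25, seed=3)
features = {(t.subject_id, t.trial_id): extract_features(t.sequence, assessment_preset())
            for t in cohort.trials}
registries = loso_train(features, cohort.labels, canonical_registry(),
                        seed=3, config=AssessConfig())

print(f"{len(cohort)} trials, {len(registries)} leave-one-subject-out folds")
print(f"{'trial':10s} {'outcome':8s} {'injected fault':14s} flags")
for t in cohort.trials:
    a = classify_movement(registries[t.subject_id],
                          features[(t.subject_id, t.trial_id)], AssessConfig())
    kinds = {f.kind for f in a.compensation_flags}
    fault = ",".join(t.truth.faults) or "-"
    print(f"{t.subject_id}/{t.trial_id:6s} {a.outcome:8s} {fault:14s} "
          f"{','.join(sorted(kinds)) or '-'}")
# Faulted trials surface flags (extra transitions, low-likelihood windows,
# timing anomalies); clean trials stay largely unflagged. Outcomes are
# graded against thresholds calibrated from each subject's peers - with
# only four peers per fold the grading is crude, so borderline subjects can
# rate below good even when unflagged; the flag column is the reliable
# fault indicator at this cohort size.
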