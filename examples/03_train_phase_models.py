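"""Fit the 4-state movement-phase HMM and check state-count selection.

The hip model decomposes the exercise into rest / raise / hold / return.
The BIC scan demonstrates state-count recovery on data drawn from the
fitted model itself; on raw kinematic ramps extra states keep subdividing
the continuous transitions, which is why the published trainer leaves the
state count as a therapist-set parameter with BIC as guidance.
"""

import numpy as np

from rehabmotion import SyntheticMotionSpec, simulate_abduction
from rehabmotion.assessment import relabel_states_by_onset, run_length_encode
from rehabmotion.features import assessment_preset, extract_features
from rehabmotion.hmm import baum_welch_fit, bic_scan, sample_sequence, viterbi_path

sequences = []
for i in range(12):
    seq, _ = simulate_abduction(SyntheticMotionSpec(seed=100 + i))
    fs = extract_features(seq, assessment_preset())
    sequences.append(fs.matrix(["hip_right_frontal_speed", "hip_right_frontal_angle"]))

model, report = baum_welch_fit(sequences, 4, seed=0)
model = relabel_states_by_onset(model, sequences)
print(f"EM converged after {report.n_iterations} iterations; "
      "state means (deg/s, deg):")
print(np.round(model.means, 1))
path = viterbi_path(model, sequences[0]).states
print("decoded phases of one trial (state, length):",
      [(s, l) for s, _, l in run_length_encode(path)])
# The decoded path reads rest -> raise -> hold -> return -> rest.

samples = [sample_sequence(model, 340, seed=i) for i in range(12)]
table, best = bic_scan(samples, state_range=range(2, 7), n_folds=3, seed=0)
print("\ncross-validated BIC on model-drawn data (lower is better):")
print(table.to_string(index=False))
print(f"recommended state count: {best} (the generating model has 4)")
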