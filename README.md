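# rehabmotion

Automatic quality assessment of therapeutic movements from depth-camera
skeletal streams, built around an ensemble of Gaussian-emission hidden
Markov models (HMMs).

Physical tele-rehabilitation after hip replacement asks patients to perform
exercises such as hip abduction at home, without a therapist watching. The
open problem is not recognizing *which* movement was performed but judging
*how well*: did the leg reach its range of motion, did the trunk move in
time with the hip, did the patient compensate (trunk sway, pelvis drift,
balance loss)? `rehabmotion` implements the full analysis chain for that
judgement, from raw 25-joint skeletal frames to a good / fair / bad outcome
with localized, directed error feedback. It is aimed at researchers in
movement analysis and rehabilitation informatics who work from Python.

## The model

A trial is a time series of feature vectors $o_1,\dots,o_n$ extracted from
the skeleton in a body-anchored *personal coordinate system* (PCS: lateral,
vertical and sagittal axes built per frame from the hip line and the floor
normal, so features are invariant to where the subject stands and faces).
The canonical four-channel vector is hip-center speed and shoulder-center
speed (m/s, 15-frame buffered), and the frontal-plane hip angle (deg, via
the cosine law) with its angular speed (deg/s).

Each movement aspect gets its own HMM over hidden phase states
$h_1,\dots,h_n$ with joint probability

$$p(o,h) = \pi(h_1)\,\varepsilon_{h_1}(o_1)\prod_{i=2}^{n}
T_{h_{i-1},h_i}\,\varepsilon_{h_i}(o_i),$$

with initial distribution $\pi$, transition matrix $T$ and per-state
diagonal-Gaussian emissions $\varepsilon_l$. For hip abduction the hip
model has 4 states (rest, raise, hold, return) and the trunk model 3
(quiet, sway out, sway back). Parameters are estimated by multi-sequence
Baum–Welch EM on the correct executions of a subject's peers
(leave-one-subject-out); the state count can be chosen by cross-validated
BIC ($k\ln N - 2\ln L$) over 2–10 states. At assessment time the forward
algorithm scores sliding windows (localizing errors), the Viterbi path is
compared against reference visit/duration/order profiles of correct
executions (detecting added, missing, elongated or shortened phases), and
timing ratios quantify movement symmetry (time-to-peak over
time-to-return) and trunk–hip synchronicity (< 1 means the trunk moved
before the hip). Flags and window likelihoods aggregate into a single
good / fair / bad outcome.

No recorded patient data ships with the package; `rehabmotion.synth`
generates seeded hip-abduction cohorts with per-subject idiosyncrasies and
five injectable fault classes (trunk–hip shift, raise/return asymmetry,
balance wobble, pelvis drift, reduced range of motion).

## Worked example

`examples/04_assess_cohort.py` simulates a 5-subject cohort, trains the
registry leave-one-subject-out and assesses every trial:

```
30 trials, 5 leave-one-subject-out folds
trial      outcome  injected fault flags
s3/t6      fair     trunk_shift    incoordination
s4/t1      fair     trunk_shift    incoordination
s4/t2      good     -              -
s4/t4      good     -              -
s4/t5      bad      reduced_rom    elongated_state,incoordination,low_likelihood
s5/t2      bad      asymmetry      extra_transition
s5/t3      bad      wobble         extra_transition,low_likelihood
...
```

Each row shows the assessment outcome, the fault the generator injected
(ground truth the assessor never sees) and the flags the blueprint raised:
the trunk-shift trials are caught by the trunk–hip timing statistic, the
reduced range of motion by low window likelihoods and an elongated raise
phase, and the balance wobble by an extra state transition in the trunk
model. `examples/05_timing_ratios.py` prints the timing ratios themselves:

```
correct execution: symmetry 1.00 (normalized 1.00), synchronicity 1.12 (normalized 0.89)
trunk advanced 30 frames: symmetry 1.00 (normalized 1.00), synchronicity 0.68 (normalized 0.68)
```

Ratios above 1 are reported with their reciprocal in the normalized form,
so averages over trials stay orientation-invariant.

The other examples cover trial simulation and fault injection (01),
feature extraction (02) and HMM training with BIC state-count selection
(03). `rehabmotion.workflows` offers the same pipeline as file-based
functions (`run_simulate`, `run_train`, `run_bic`, `run_assess`) for batch
use.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end result from scratch: it simulates a
nine-subject, eight-repetition hip-abduction cohort with 25% faulted
trials, trains the two-model registry leave-one-subject-out, assesses all
72 trials and prints the detection summary (faulted trials flagged, clean
trials falsely flagged, outcome counts and the average normalized timing
ratios of clean trials) before writing the results file.
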