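# Packaged default generator configuration.
#
# Phase durations, referential timing (instructor anticipatory lead, worker
# referent latency), unmapped-gaze rates, per-phase gaze leads, and the
# per-phase coupling strengths are calibrated so the simulated corpus
# reproduces the study-scale descriptive statistics and per-phase peak
# alignment values this package's analyses are exercised against.  The
# per-phase target distributions additionally reproduce the qualitative
# strongest-edge pattern of the phase mean networks (see docs/methods.md).
phase_duration_mean_s:
  pre_reference: 1.9
  reference: 1.32
  post_reference: 0.78
  action: 1.68
  post_action: 0.81
phase_duration_cv: 0.4
instructor_dist:
  pre_reference:
    reference: 0.35
    other: 0.3
    target: 0.12
    person: 0.05
    unmapped: 0.18
  reference:
    reference: 0.45
    other: 0.2
    target: 0.05
    person: 0.1
    unmapped: 0.2
  post_reference:
    reference: 0.38
    other: 0.2
    target: 0.12
    person: 0.1
    unmapped: 0.2
  action:
    reference: 0.08
    other: 0.34
    target: 0.22
    person: 0.1
    unmapped: 0.26
  post_action:
    reference: 0.12
    other: 0.33
    target: 0.15
    person: 0.12
    unmapped: 0.28
worker_dist:
  pre_reference:
    reference: 0.02
    other: 0.36
    target: 0.3
    person: 0.07
    unmapped: 0.25
  reference:
    reference: 0.05
    other: 0.33
    target: 0.29
    person: 0.07
    unmapped: 0.26
  post_reference:
    reference: 0.36
    other: 0.24
    target: 0.15
    person: 0.05
    unmapped: 0.2
  action:
    reference: 0.04
    other: 0.17
    target: 0.45
    person: 0.05
    unmapped: 0.29
  post_action:
    reference: 0.03
    other: 0.29
    target: 0.29
    person: 0.08
    unmapped: 0.31
coupling_rho:
  pre_reference: 0.34
  reference: 0.546
  post_reference: 0.5
  action: 0.247
  post_action: 0.189
lead_ms:
  pre_reference: 0
  reference: 700
  post_reference: -300
  action: -50
  post_action: 300
dwell_mean_ms: 300
dwell_cv: 0.4
min_dwell_ms: 40
instructor_ref_lead_mean_s: 1.45
instructor_ref_lead_cv: 0.3
worker_ref_latency_mean_s: 1.65
worker_ref_latency_cv: 0.2
repair_prob: 0.35
repair_worker_deltas:
  pre_reference:
    target: 0.12
    other: -0.12
  reference:
    other: 0.15
    target: -0.09
    reference: -0.03
    person: -0.03
  post_reference:
    other: 0.12
    reference: -0.12
n_ingredients: 23
inter_sequence_gap_ms: 400
segment_ms: 50
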