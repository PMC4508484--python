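"""Compare gaze networks of sequences with vs. without conversational repair.

Repair sequences perturb the worker's gaze (more non-referent gaze during
and after the reference; more bread-directed gaze before it).  Units are
dyad-interaction x phase x repair inside one shared ENA space; each phase
gets a centroid t-test on dimension 2 plus a difference network.  A larger
|t| with p < 0.05 in the early phases means breakdowns are visible in gaze
before any verbal repair happens.
"""
import gazecoord as gc
from gazecoord import group_comparison as gcmp

corpus = gc.generate(gc.default_config(), 13, 2, 15, seed=42)
segments = gc.discretize(corpus.fixations, corpus.sequences)
report = gcmp.repair_report(segments, dimension=1)
print(report.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
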