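"""Predict the sequence phase from short windows of raw gaze.

The ENA space is fitted with one dyad held out; random 200-ms and 1000-ms
gaze windows from that dyad are projected into the space and labelled by
the nearest phase centroid.  Accuracy far above the 20% chance level shows
the phase structure is recoverable from gaze alone, and longer windows
confuse less.
"""
import gazecoord as gc
from gazecoord import phase_prediction as pp

corpus = gc.generate(gc.default_config(), 13, 2, 15, seed=42)
segments = gc.discretize(corpus.fixations, corpus.sequences)
for window_ms in (200, 1000):
    cm = pp.predict_phases(segments, corpus.sequences, held_out_dyad="d00",
                           window_ms=window_ms, n_per_phase=50, seed=7)
    print(f"\n{window_ms}-ms windows: accuracy {cm.accuracy:.3f} "
          f"({cm.n_uncodable} uncodable windows excluded)")
    print(cm.counts.to_string())
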