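"""Scan gaze alignment over time lags and recover each phase's optimal lag.

Alignment at lag tau = fraction of 50-ms segments where the worker gazes
at the same object the instructor gazed at tau earlier (positive lag =
instructor leads).  The generator's default leads are 0 / 700 / -300 /
-50 / 300 ms; the scan recovers them along with the peak alignment level.
"""
import gazecoord as gc
from gazecoord import lag_alignment as la

cfg = gc.default_config()
corpus = gc.generate(cfg, 13, 2, 15, seed=42)
segments = gc.discretize(corpus.fixations, corpus.sequences)
curves = la.alignment_curves(segments)
print(f"{'phase':16s}{'optimal lag':>12s}{'alignment':>11s}{'configured lead':>17s}")
for phase in gc.PHASES:
    lag, value = la.optimal_lag(curves[phase])
    print(f"{phase:16s}{lag:>9d} ms{100*value:>10.1f}%{cfg.lead_ms[phase]:>14d} ms")
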