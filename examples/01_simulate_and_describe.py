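"""Generate a synthetic dyad-gaze corpus and print its descriptive statistics.

The corpus mimics a table-top instruction task: 13 dyads, two interactions
each, 15 reference-action sequences per interaction.  The printed numbers
are the study-scale descriptives the generator is calibrated to: shared
gaze toward the same target category (~31%), near-absent mutual gaze
(<1%), the instructor's anticipatory referent fixation (~1.3 s before the
verbal reference) and the worker's referent latency (~1.65 s after it).
"""
import gazecoord as gc

cfg = gc.default_config()
corpus = gc.generate(cfg, n_dyads=13, n_interactions=2, n_sequences=15, seed=42)
segments = gc.discretize(corpus.fixations, corpus.sequences)
stats = gc.descriptive_stats(corpus.fixations, corpus.sequences, segments)

print(f"corpus: {len(corpus.fixations)} fixations, {len(corpus.sequences)} sequences, "
      f"{len(segments)} coded 50-ms segments")
print(f"shared gaze, same target category : {stats.same_target_pct:.2f} %")
print(f"shared gaze, same object (AOI)    : {stats.same_object_pct:.2f} %")
print(f"mutual gaze                       : {stats.mutual_gaze_pct:.2f} %")
print(f"instructor first-referent lead    : {stats.instructor_ref_lead_s:.2f} s before reference onset")
print(f"worker referent latency           : {stats.worker_ref_latency_s:.2f} s after reference onset")
print(f"instructor referent fixations     : {stats.instructor_ref_fix_count:.2f} before the reference")
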