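"""Build the phase-resolved ENA space and show that gaze coordination cycles.

Units of analysis are dyad-interaction x phase (130 networks for the
default corpus).  Each unit's co-occurrence network is normalised,
centred, and projected by SVD; phase centroids separate and trace a cycle
through the plane as a sequence progresses.  Printed: per-phase centroid
coordinates and the strongest edge of each phase's mean network.
"""
import numpy as np
import gazecoord as gc
from gazecoord import ena_core

corpus = gc.generate(gc.default_config(), 13, 2, 15, seed=42)
segments = gc.discretize(corpus.fixations, corpus.sequences)
units = ena_core.accumulate_units(segments)
space = ena_core.build_space(units, d=2)
ena_core.position_nodes(space, units)
print(f"{len(units)} units; variance explained: "
      f"{100*space.variance_explained[0]:.1f}% + {100*space.variance_explained[1]:.1f}%")

phase_level = np.asarray(units.index.get_level_values("phase"))
for k, phase in enumerate(gc.PHASES):
    sel = phase_level == k
    summ = ena_core.mean_network(units[sel], space.projections[sel], label=phase)
    strongest = summ.mean_network.idxmax()
    print(f"{phase:15s} centroid ({summ.centroid[0]:+.3f}, {summ.centroid[1]:+.3f})  "
          f"strongest edge: {strongest} ({summ.mean_network.max():.3f})")
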