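import numpy as np
import pandas as pd
import pytest

import gazecoord as gc
from gazecoord.gaze_model import PHASES


@pytest.fixture(scope="session")
def default_cfg():
    return gc.default_config()


@pytest.fixture(scope="session")
def small_corpus(default_cfg):
    """4 dyads x 2 interactions x 6 sequences under the packaged defaults."""
    return gc.generate(default_cfg, n_dyads=4, n_interactions=2, n_sequences=6, seed=11)


@pytest.fixture(scope="session")
def small_segments(small_corpus):
    return gc.discretize(small_corpus.fixations, small_corpus.sequences)


@pytest.fixture(scope="session")
def study_corpus(default_cfg):
    """Study-scale corpus: 13 dyads x 2 interactions x 15 sequences."""
    return gc.generate(default_cfg, n_dyads=13, n_interactions=2, n_sequences=15, seed=42)


@pytest.fixture(scope="session")
def study_segments(study_corpus):
    return gc.discretize(study_corpus.fixations, study_corpus.sequences)


# ---------------------------------------------------------------------------
# hand-construction helpers
# ---------------------------------------------------------------------------

def seq_row(dyad="d0", inter=1, seq=0, referent="ing01", bounds=(0, 1000, 2000, 3000, 4000, 5000), repair=0):
    """One sequence-table row from six phase-boundary timestamps."""
    row = {
        "dyad_id": dyad,
        "interaction_id": inter,
        "seq_index": seq,
        "referent_id": referent,
        "repair": repair,
        "reference_onset_ms": bounds[1],
    }
    for k, p in enumerate(PHASES):
        row[f"{p}_start_ms"] = bounds[k]
        row[f"{p}_end_ms"] = bounds[k + 1]
    return row


def seq_table(*rows):
    return pd.DataFrame(list(rows))


def fix_table(spans, dyad="d0", inter=1, role="instructor"):
    """Fixation table from (t_start, t_end, aoi) triples for one participant,
    or (dyad, inter, role, t0, t1, aoi) six-tuples for mixed tables."""
    rows = []
    for s in spans:
        if len(s) == 3:
            rows.append(dict(dyad_id=dyad, interaction_id=inter, role=role,
                             t_start_ms=s[0], t_end_ms=s[1], aoi_raw=s[2]))
        else:
            rows.append(dict(dyad_id=s[0], interaction_id=s[1], role=s[2],
                             t_start_ms=s[3], t_end_ms=s[4], aoi_raw=s[5]))
    return pd.DataFrame(rows)
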