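"""Shared settings for the numbered analysis scripts.

The drivers re-derive every input deterministically from these seeds, so
each script can run standalone.  The demo scale (2 × 10 samples × 50,000
reads) keeps each step under a minute; the full study scale used by the
acceptance checks (2 × 20 × 200,000) is a parameter change here.
"""

from pathlib import Path

import bilescreen as bs

RESULTS = Path(__file__).resolve().parent.parent / "results"

COMMUNITY_SEED = 20140
COHORT_SEED = 2014

GROUPS = [("control", 10), ("disease", 10)]
READ_COUNT = 50_000
ERROR_RATE = 0.01
EFFECT = 0.5  # disease-group multiplier on cluster-1 bsh genomes


def community():
    return bs.build_community(COMMUNITY_SEED)


def cohort_spec():
    return bs.CohortSpec(
        groups=GROUPS,
        base_weights=bs.BASE_WEIGHTS,
        effects=bs.disease_effects(EFFECT),
        compensator="g_background",
        read_count=READ_COUNT,
        error_rate=ERROR_RATE,
        seed=COHORT_SEED,
    )
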