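"""Deterministic stream splitting for the synthetic-cohort generator.

All randomness derives from one root seed through ``numpy.random.SeedSequence``
spawning, with a fixed, named stream per simulation concern.  Re-running a
single stage (e.g. re-rendering one patient's sections) therefore reproduces
exactly the draws of a full cohort run.
"""

from __future__ import annotations

import numpy as np

#: Order matters: streams are spawned positionally from the root sequence.
STREAMS = (
    "truth",        # true hypoxic fractions, lesion geometry, pairing
    "field",        # per-patient spatial hypoxia fields
    "stain",        # per-section stain amplitude and optical-density noise
    "scores",       # pathologist ordinal scores
    "expression",   # probe-level expression values and kit assignment
    "clinical",     # clinical-marker draws
    "survival",     # event and censoring times
)


def split_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Return one independent ``Generator`` per named stream for ``seed``."""
    root = np.random.SeedSequence(int(seed))
    children = root.spawn(len(STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(STREAMS, children)}


def patient_seed_sequences(seed: int, stream: str, n: int) -> list[np.random.SeedSequence]:
    """Per-patient child sequences of one stream, for independent re-rendering."""
    idx = STREAMS.index(stream)
    child = np.random.SeedSequence(int(seed)).spawn(len(STREAMS))[idx]
    return child.spawn(n)
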