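"""Deterministic seed streams.

All randomness in the pipeline flows from a single root seed through
:class:`numpy.random.SeedSequence` spawn keys, so that results are
independent of task scheduling and worker count. Each pipeline stage has a
fixed integer tag and derives per-task streams from (stage, depth,
combo, ...) coordinates rather than from execution order.
"""

from __future__ import annotations

import numpy as np

# stage tags used in spawn keys
STAGE_SP = 1
STAGE_BOOT = 2
STAGE_IMPUTE = 3
STAGE_SYNTH = 4


def stream(root_seed: int, *key: int) -> np.random.SeedSequence:
    """SeedSequence for a task addressed by integer coordinates."""
    return np.random.SeedSequence(int(root_seed), spawn_key=tuple(int(k) for k in key))


def as_int_seed(seq: np.random.SeedSequence) -> int:
    """Collapse a SeedSequence into a non-negative 31-bit integer seed.

    scikit-learn estimators take plain integer ``random_state``; 31 bits
    keeps the value portable.
    """
    return int(seq.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
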