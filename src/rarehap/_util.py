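"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (for x >= 0).

    Used for MAC boundaries derived from percent-of-haplotype-count caps,
    e.g. ``round_half_up(0.01 * 20000) == 200``.
    """
    return int(math.floor(x + 0.5))


def child_seed(master: int, stream: int) -> int:
    """Deterministic 31-bit child seed for sub-step ``stream`` of ``master``.

    Each pipeline stage consumes its own independent stream so that a whole
    multi-step run is reproducible from a single integer.
    """
    ss = np.random.SeedSequence([int(master), int(stream)])
    return int(ss.generate_state(1)[0] >> 1)
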