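"""Small shared helpers: seed fan-out and dataframe checks."""

from __future__ import annotations

import numpy as np


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1, dtype=np.uint32)[0] % (2**31)) for s in ss.spawn(n)]


def rng_from(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
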