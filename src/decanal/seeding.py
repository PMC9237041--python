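"""Canonical seed derivation: one master seed, named independent streams."""

from __future__ import annotations

import numpy as np

__all__ = ["spawn_ints"]


def spawn_ints(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit integer seeds from a master seed via
    ``numpy.random.SeedSequence`` spawning (the scheme used throughout the
    package for replicate studies)."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]
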