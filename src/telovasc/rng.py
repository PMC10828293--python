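"""Named random substreams derived from a single master seed.

Every stochastic component of the simulator draws from its own
deterministic substream so that adding draws to one component never
perturbs another, and identical configs yield byte-identical tables.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def child_seed(seed: int, index: int) -> int:
    """A derived 31-bit seed for replicate ``index`` of a study seeded by ``seed``."""
    ss = np.random.SeedSequence([int(seed), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
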