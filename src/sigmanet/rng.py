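"""Named, independent random streams.

Every stochastic component draws from its own :class:`numpy.random.Generator`
spawned from a single root seed, so that toggling one process (e.g. mate
choice) does not shift the draws consumed by another.
"""

from __future__ import annotations

import numpy as np

#: Stream names used by the spatial simulator, in spawn order.
SIM_STREAMS = ("placement", "mating", "counts", "dispersal", "survival")


def spawn_streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    """Return one independent Generator per name, derived from ``seed``."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def derive_seed(seed: int, *salt: int) -> int:
    """Deterministically derive a sub-seed below 2**31 (msprime-safe, >= 1)."""
    ss = np.random.SeedSequence([int(seed)] + [int(s) for s in salt])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 2)) + 1
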