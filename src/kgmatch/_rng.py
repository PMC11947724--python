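"""Seeded random-number plumbing shared by the Monte-Carlo stages."""

from __future__ import annotations

import numpy as np


class CountingGenerator:
    """A numpy ``Generator`` wrapper that counts uniform variates drawn.

    The matchers thread a single instance through every Monte-Carlo stage of
    a run, which both fixes the draw order (node roulette before edge
    roulette, pattern edges in topological order, dc before cv) and lets a
    run report its total sampling effort.
    """

    def __init__(self, seed: int) -> None:
        self.generator = np.random.default_rng(seed)
        self.n_drawn = 0

    def random(self, size: int | None = None) -> np.ndarray | float:
        self.n_drawn += 1 if size is None else int(np.prod(size))
        return self.generator.random(size)
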