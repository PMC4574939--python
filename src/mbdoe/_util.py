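"""Small shared utilities: simulation counting and seed handling."""
from __future__ import annotations

import numpy as np


class SimCounter:
    """Counts ODE model simulations per pipeline stage."""

    def __init__(self):
        self.stages: dict[str, int] = {}
        self._stage = "default"

    def stage(self, name: str) -> "SimCounter":
        self._stage = name
        self.stages.setdefault(name, 0)
        return self

    def add(self, n: int = 1) -> None:
        self.stages[self._stage] = self.stages.get(self._stage, 0) + n

    @property
    def total(self) -> int:
        return sum(self.stages.values())


def spawn_rngs(seed, n: int) -> list[np.random.Generator]:
    """Independent generators for pipeline stages, all derived from one root."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
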