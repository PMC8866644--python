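"""Block-design paradigm: timing of rest, task and control blocks.

The default paradigm is a 2-minute initial rest followed by six 30-s task
blocks (overt picture naming, 2-s stimuli) alternating with six 30-s control
blocks (reciting weekdays), 480 s in total. Task blocks come first after the
rest and the two block types tile the post-rest interval without overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DesignError


@dataclass(frozen=True)
class BlockDesign:
    initial_rest_s: float
    n_task_blocks: int
    n_control_blocks: int
    block_s: float
    stimulus_s: float
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.initial_rest_s < 0:
            raise DesignError("initial rest must be >= 0")
        for name in ("block_s", "stimulus_s", "sampling_rate"):
            if getattr(self, name) <= 0:
                raise DesignError(f"{name} must be > 0")
        if self.n_task_blocks < 1:
            raise DesignError("need at least one task block")
        if self.n_control_blocks not in (self.n_task_blocks, self.n_task_blocks - 1):
            raise DesignError(
                "task and control blocks must alternate (n_control in "
                "{n_task, n_task - 1})"
            )

    @property
    def duration_s(self) -> float:
        return self.initial_rest_s + (self.n_task_blocks + self.n_control_blocks) * self.block_s

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))

    def _indicator(self, which: str) -> np.ndarray:
        t = np.arange(self.n_samples) / self.sampling_rate
        ind = np.zeros(self.n_samples)
        n_blocks = self.n_task_blocks + self.n_control_blocks
        for b in range(n_blocks):
            start = self.initial_rest_s + b * self.block_s
            is_task = b % 2 == 0  # task first after rest
            if (which == "task") == is_task:
                ind[(t >= start) & (t < start + self.block_s)] = 1.0
        return ind

    def task_indicator(self) -> np.ndarray:
        """Boxcar that is 1 during task blocks, sampled at the design rate."""
        return self._indicator("task")

    def control_indicator(self) -> np.ndarray:
        return self._indicator("control")


def default_design(sampling_rate: float) -> BlockDesign:
    return BlockDesign(
        initial_rest_s=120.0,
        n_task_blocks=6,
        n_control_blocks=6,
        block_s=30.0,
        stimulus_s=2.0,
        sampling_rate=sampling_rate,
    )
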