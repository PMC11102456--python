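"""Block designs for the dynamic localizer task.

The default run comprises two 18-s blocks of each of five stimulus
conditions plus three rest blocks (beginning, middle, end), giving a
234-volume run at TR = 1 s. Rest blocks are 18 s each (three 6-s colour
segments) so the block timeline tiles the run exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .registry import CONDITIONS

__all__ = ["Block", "BlockDesign", "make_block_design"]

REST = "rest"


@dataclass(frozen=True)
class Block:
    condition: str
    onset: float     # seconds
    duration: float  # seconds


@dataclass
class BlockDesign:
    """An ordered, non-overlapping sequence of blocks tiling a run."""

    blocks: list[Block]
    tr: float
    n_volumes: int
    conditions: tuple[str, ...] = field(default=CONDITIONS)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        prev_end = 0.0
        for b in self.blocks:
            if b.duration <= 0:
                raise ValueError(f"non-positive block duration: {b}")
            if b.onset < prev_end - 1e-9:
                raise ValueError("blocks overlap or are unsorted")
            prev_end = b.onset + b.duration
        total = sum(b.duration for b in self.blocks)
        if abs(total - self.n_volumes * self.tr) > 1e-6:
            raise ValueError(
                f"block durations sum to {total}s but run has "
                f"{self.n_volumes} volumes at TR={self.tr}s"
            )

    def condition_order(self) -> list[str]:
        return [b.condition for b in self.blocks]

    def blocks_for(self, condition: str) -> list[Block]:
        return [b for b in self.blocks if b.condition == condition]


def make_block_design(
    *,
    block_duration_s: float = 18.0,
    rest_duration_s: float = 18.0,
    blocks_per_condition: int = 2,
    tr: float = 1.0,
    conditions: tuple[str, ...] = CONDITIONS,
    seed: int | np.random.Generator | None = 0,
) -> BlockDesign:
    """Assemble a localizer run: randomized condition blocks, rest at the
    beginning, middle and end.

    With the defaults (5 conditions x 2 x 18 s + 3 x 18 s rest, TR = 1 s)
    the run is 234 volumes long.
    """
    if block_duration_s <= 0 or rest_duration_s <= 0:
        raise ValueError("durations must be positive")
    if blocks_per_condition < 1:
        raise ValueError("blocks_per_condition must be >= 1")
    if len(conditions) < 1:
        raise ValueError("need at least one condition")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = list(conditions) * blocks_per_condition
    order = [labels[i] for i in rng.permutation(len(labels))]

    half = len(order) // 2
    sequence: list[str] = [REST] + order[:half] + [REST] + order[half:] + [REST]

    blocks: list[Block] = []
    t = 0.0
    for cond in sequence:
        dur = rest_duration_s if cond == REST else block_duration_s
        blocks.append(Block(cond, t, dur))
        t += dur

    n_volumes = int(round(t / tr))
    if abs(n_volumes * tr - t) > 1e-6:
        raise ValueError("run duration is not a whole number of volumes")
    return BlockDesign(blocks=blocks, tr=tr, n_volumes=n_volumes, conditions=conditions)
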