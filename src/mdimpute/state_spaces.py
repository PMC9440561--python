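"""Partition pseudo-time-ordered cells into consecutive cell-state spaces.

A *space* is a block of ``m`` consecutive cells in pseudo-time order,
treated as sharing an expression state. ``m`` scales with the number of
cells J as ``m = 5(ceil(J/1000) + 1)``; a trailing remainder smaller than
``min_last`` cells is merged into the preceding block so per-space
statistics stay well-posed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["StatePartition", "compute_m", "partition_cells"]


@dataclass
class StatePartition:
    """Disjoint consecutive blocks of pseudo-time-ordered cell positions."""

    m: int
    S: int
    blocks: list
    min_last: int = 3

    def __post_init__(self) -> None:
        self.blocks = [np.asarray(b, dtype=int) for b in self.blocks]
        if self.S != len(self.blocks):
            raise ValueError("S does not match number of blocks")
        j = sum(len(b) for b in self.blocks)
        if not np.array_equal(np.concatenate(self.blocks), np.arange(j)):
            raise ValueError("blocks must be consecutive and cover all cells")

    @property
    def n_cells(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def sizes(self) -> list:
        return [len(b) for b in self.blocks]

    def space_of(self) -> np.ndarray:
        """Space index of every ordered cell position."""
        out = np.empty(self.n_cells, dtype=int)
        for s, b in enumerate(self.blocks):
            out[b] = s
        return out

    def to_frame(self, order=None, cell_ids=None) -> pd.DataFrame:
        j = self.n_cells
        space = self.space_of()
        rows = []
        for rank in range(j):
            orig = order[rank] if order is not None else rank
            cid = cell_ids[orig] if cell_ids is not None else str(orig)
            rows.append((cid, rank, int(space[rank])))
        return pd.DataFrame(rows, columns=["cell_id", "rank", "space_index"])


def compute_m(J: int) -> int:
    """Cells per space: ``m = 5(ceil(J/1000) + 1)``."""
    if J < 1:
        raise ValueError("J must be positive")
    return 5 * (math.ceil(J / 1000) + 1)


def partition_cells(order, m: int, min_last: int = 3) -> StatePartition:
    """Split the ordered cells into consecutive blocks of ``m``.

    The trailing remainder is merged into the previous block when it has
    fewer than ``min_last`` cells. ``J < m`` degenerates to a single block
    (logged, not an error).
    """
    order = np.asarray(order, dtype=int)
    j = order.size
    if m < 2:
        raise ValueError("m must be at least 2")
    if j < m:
        logger.warning("J=%d < m=%d: using a single space with all cells", j, m)
        return StatePartition(m=m, S=1, blocks=[np.arange(j)], min_last=min_last)
    edges = list(range(0, j, m))
    blocks = [np.arange(a, min(a + m, j)) for a in edges]
    if len(blocks) > 1 and len(blocks[-1]) < min_last:
        tail = blocks.pop()
        blocks[-1] = np.concatenate([blocks[-1], tail])
    return StatePartition(m=m, S=len(blocks), blocks=blocks, min_last=min_last)
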