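"""Confidence masking: forbid design at low-confidence positions.

Predicted structures carry per-residue confidence (pLDDT, 0-100). Design is
disallowed at every position below a confidence threshold, and, because a
low-confidence stretch makes its immediate surroundings unreliable too, a
fixed number of flanking positions on each side of every such stretch is
restricted as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfidenceMask", "build_mask", "designable_positions"]


@dataclass
class ConfidenceMask:
    """Per-position designable/restricted flags (1-based positions)."""

    length: int
    restricted: frozenset[int]
    threshold: float
    flank: int

    def __post_init__(self) -> None:
        self.restricted = frozenset(self.restricted)
        if any(p < 1 or p > self.length for p in self.restricted):
            raise ValueError("restricted positions out of range")

    def is_designable(self, position: int) -> bool:
        return 1 <= position <= self.length and position not in self.restricted


def build_mask(
    plddt: np.ndarray | list[float], threshold: float = 90.0, flank: int = 2
) -> ConfidenceMask:
    """Restrict every sub-threshold stretch plus ``flank`` positions per side.

    For each maximal run ``[i..j]`` with ``plddt < threshold`` (strict), the
    closed interval ``[i-flank .. j+flank]`` clipped to ``[1..L]`` is
    restricted. Nothing else is.
    """
    plddt = np.asarray(plddt, dtype=float)
    if plddt.size == 0:
        raise ValueError("plddt vector is empty")
    if not (0.0 <= threshold <= 100.0):
        raise ValueError("threshold must be in [0, 100]")
    if flank < 0:
        raise ValueError("flank must be non-negative")
    L = plddt.size
    low = plddt < threshold
    restricted: set[int] = set()
    i = 0
    while i < L:
        if low[i]:
            j = i
            while j + 1 < L and low[j + 1]:
                j += 1
            lo = max(1, i + 1 - flank)
            hi = min(L, j + 1 + flank)
            restricted.update(range(lo, hi + 1))
            i = j + 1
        else:
            i += 1
    return ConfidenceMask(L, frozenset(restricted), threshold, flank)


def designable_positions(mask: ConfidenceMask) -> list[int]:
    """Ordered complement of the restricted set."""
    return [p for p in range(1, mask.length + 1) if p not in mask.restricted]
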