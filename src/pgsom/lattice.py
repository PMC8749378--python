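"""Integer-grid topology helpers for the growing lattice.

The map lives on an unbounded 2-D integer grid: growth may push neuron
positions negative and pruning may punch holes, so no array geometry is
assumed anywhere.  Connectivity is the 4-neighborhood (von Neumann);
growth always targets the four axis-adjacent slots around a winner.
"""

from __future__ import annotations

from typing import List, Tuple

GridPos = Tuple[int, int]

# (row, col) offsets in the fixed order [up, down, left, right]; the order
# is part of the contract because downstream tie-breaking depends on it.
NEIGHBOR_OFFSETS: Tuple[GridPos, ...] = ((-1, 0), (1, 0), (0, -1), (0, 1))


def neighbor_positions(pos: GridPos) -> List[GridPos]:
    """Return the four axis-adjacent positions as [up, down, left, right]."""
    r, c = pos
    return [(r + dr, c + dc) for dr, dc in NEIGHBOR_OFFSETS]


def opposite_position(winner: GridPos, new_pos: GridPos) -> GridPos:
    """Position mirrored across ``winner`` from ``new_pos``.

    Used for weight interpolation of a freshly grown neuron: the neuron
    opposite the growth slot (when present) defines a linear extrapolation
    direction through the winner.
    """
    return (2 * winner[0] - new_pos[0], 2 * winner[1] - new_pos[1])


def is_boundary(state, pos: GridPos) -> bool:
    """True iff ``pos`` has at least one unoccupied 4-neighbor slot.

    ``pos`` must hold a live neuron; querying an empty slot is a caller bug.
    """
    if not state.occupied(pos):
        raise ValueError(f"is_boundary queried on unoccupied position {pos}")
    return any(not state.occupied(p) for p in neighbor_positions(pos))


def free_neighbor_positions(state, pos: GridPos) -> List[GridPos]:
    """Unoccupied 4-neighbor slots of ``pos``, in the fixed neighbor order."""
    return [p for p in neighbor_positions(pos) if not state.occupied(p)]


def occupied_neighbor_positions(state, pos: GridPos) -> List[GridPos]:
    """Occupied 4-neighbor slots of ``pos``, in the fixed neighbor order."""
    return [p for p in neighbor_positions(pos) if state.occupied(p)]
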