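"""Field geometry and single-recipient drainage routing.

A grazed field is discretised into square cells labelled like spreadsheet
coordinates ("E4" = column E, row 4), with row numbers increasing southwards.
Each cell drains to at most one of its eight compass neighbours or directly to
the field outlet (``OUTLET``), and may receive at most one upstream
contributor.  Under these constraints the drainage graph decomposes into
disjoint *flow lines*: maximal chains of cells whose outflows are ultimately
summed at the outlet flume.

The module validates direction maps, derives a deterministic simulation order
(every cell after its upstream contributor), decomposes the graph into flow
lines, and estimates per-cell terrain slope from a DEM with Horn's
eight-neighbour finite-difference operator.
"""
from __future__ import annotations

import heapq
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import (
    CycleError,
    DanglingError,
    ShapeError,
    TwoUpstreamError,
)

OUTLET = "OUTLET"

#: Compass token -> (delta column, delta row).  Rows increase southwards,
#: so "N" decreases the row number.
DIRECTION_OFFSETS: dict[str, tuple[int, int]] = {
    "N": (0, -1),
    "NE": (1, -1),
    "E": (1, 0),
    "SE": (1, 1),
    "S": (0, 1),
    "SW": (-1, 1),
    "W": (-1, 0),
    "NW": (-1, -1),
}

_ID_RE = re.compile(r"^([A-Z])([0-9]+)$")


def parse_cell_id(cell_id: str) -> tuple[int, int]:
    """Return (column index, row number) for a label like ``"E4"``.

    Column A has index 0.
    """
    m = _ID_RE.match(cell_id)
    if not m:
        raise ValueError(f"malformed cell id {cell_id!r}")
    return ord(m.group(1)) - ord("A"), int(m.group(2))


def make_cell_id(col: int, row: int) -> str:
    if not 0 <= col < 26:
        raise ValueError(f"column index {col} out of range")
    return f"{chr(ord('A') + col)}{row}"


def neighbour_id(cell_id: str, direction: str) -> str:
    """Id of the 8-neighbour of *cell_id* in compass *direction*."""
    dc, dr = DIRECTION_OFFSETS[direction]
    col, row = parse_cell_id(cell_id)
    return make_cell_id(col + dc, row + dr)


@dataclass
class GridCell:
    """One square cell of the field grid.

    Parameters
    ----------
    id:
        Column-letter/row-number label, e.g. ``"E4"``.
    center:
        Planar (x, y) centre coordinates in metres; y increases southwards
        to match the row numbering.
    area:
        Cell area in m² (default 625 for a 25 m grid).
    slope:
        Dimensionless rise/run terrain slope, >= 0.
    elevation:
        Optional cell-centre elevation in metres.
    complete:
        False for boundary cells excluded from spatial map output.
    """

    id: str
    center: tuple[float, float]
    area: float = 625.0
    slope: float = 0.0
    elevation: Optional[float] = None
    complete: bool = True

    def __post_init__(self) -> None:
        parse_cell_id(self.id)  # validates the label format
        if self.area <= 0:
            raise ValueError(f"cell {self.id}: area must be > 0")
        if self.slope < 0:
            raise ValueError(f"cell {self.id}: slope must be >= 0")


@dataclass
class RoutingMap:
    """Validated single-recipient drainage graph over a set of cells."""

    cells: dict[str, GridCell]
    recipient: dict[str, str]  # cell id -> cell id or OUTLET
    outlet_cell: Optional[str] = None

    def upstream_of(self, cell_id: str) -> Optional[str]:
        """Id of the (unique) cell draining into *cell_id*, or None."""
        for src, dst in self.recipient.items():
            if dst == cell_id:
                return src
        return None

    @property
    def terminal_cells(self) -> list[str]:
        """Cells that drain directly to the outlet, sorted by id."""
        return sorted(c for c, r in self.recipient.items() if r == OUTLET)


@dataclass
class FlowLine:
    """Maximal chain of cells from a source to a terminal cell."""

    cells: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)


def build_routing(
    cells: Iterable[GridCell],
    directions: Mapping[str, str],
    outlet_cell: Optional[str] = None,
) -> RoutingMap:
    """Validate a direction map and return the routing graph.

    Every cell must carry a direction: one of the eight compass tokens or
    ``OUTLET``.  Compass directions must point at another cell of the grid.

    Raises
    ------
    TwoUpstreamError
        if two cells drain into the same recipient.
    CycleError
        if the directions form a loop.
    DanglingError
        if a chain leaves the grid anywhere other than at the outlet, or a
        cell has no direction at all.
    """
    cell_map = {c.id: c for c in cells}
    if len(cell_map) == 0:
        raise ShapeError("routing requires at least one cell")

    recipient: dict[str, str] = {}
    indegree: dict[str, int] = {cid: 0 for cid in cell_map}
    for cid in sorted(cell_map):
        if cid not in directions:
            raise DanglingError(f"cell {cid} has no drainage direction")
        token = directions[cid]
        if token == OUTLET:
            recipient[cid] = OUTLET
            continue
        if token not in DIRECTION_OFFSETS:
            raise ValueError(f"cell {cid}: unknown direction token {token!r}")
        try:
            target = neighbour_id(cid, token)
        except ValueError:
            raise DanglingError(
                f"cell {cid} drains {token} off the labelled grid"
            ) from None
        if target not in cell_map:
            raise DanglingError(f"cell {cid} drains {token} to {target}, "
                                "which is not a grid cell")
        recipient[cid] = target
        indegree[target] += 1
        if indegree[target] > 1:
            raise TwoUpstreamError(
                f"cell {target} would receive more than one upstream cell"
            )

    # Out-degree is exactly 1 (to a cell or OUTLET); any cycle is reachable
    # by following recipients from each cell.
    colour: dict[str, int] = {}  # 0 = in progress, 1 = done
    for start in cell_map:
        if start in colour:
            continue
        path = []
        node = start
        while node != OUTLET and node not in colour:
            colour[node] = 0
            path.append(node)
            node = recipient[node]
        if node != OUTLET and colour.get(node) == 0:
            raise CycleError(f"routing directions form a loop through {node}")
        for n in path:
            colour[n] = 1

    return RoutingMap(cells=cell_map, recipient=recipient,
                      outlet_cell=outlet_cell)


def topological_order(rmap: RoutingMap) -> list[str]:
    """Simulation order: sources first, every cell after its contributor.

    Ties (cells simultaneously ready) are broken lexicographically so the
    order is deterministic.
    """
    indeg = {cid: 0 for cid in rmap.cells}
    for dst in rmap.recipient.values():
        if dst != OUTLET:
            indeg[dst] += 1
    ready = [cid for cid, d in indeg.items() if d == 0]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        cid = heapq.heappop(ready)
        order.append(cid)
        dst = rmap.recipient.get(cid, OUTLET)
        if dst != OUTLET:
            indeg[dst] -= 1
            if indeg[dst] == 0:
                heapq.heappush(ready, dst)
    if len(order) != len(rmap.cells):
        raise CycleError("routing map contains a cycle")
    return order


def flow_lines(rmap: RoutingMap) -> list[FlowLine]:
    """Decompose the routing graph into its maximal disjoint chains.

    With in-degree and out-degree both <= 1 the graph is a disjoint union of
    simple chains; each starts at a source (no upstream contributor) and ends
    at a cell draining to OUTLET.  Lines are returned sorted by head cell id.
    """
    has_upstream = {dst for dst in rmap.recipient.values() if dst != OUTLET}
    sources = sorted(cid for cid in rmap.cells if cid not in has_upstream)
    lines: list[FlowLine] = []
    for src in sources:
        chain = [src]
        node = rmap.recipient[src]
        while node != OUTLET:
            chain.append(node)
            node = rmap.recipient[node]
        lines.append(FlowLine(cells=tuple(chain)))
    return lines


def slope_from_dem(elevations: np.ndarray, cell_size: float) -> np.ndarray:
    """Per-cell terrain slope (rise/run) via Horn's 8-neighbour method.

    Edge cells are handled by mirrored (symmetric) padding, so a single-cell
    grid or a constant surface yields zero slope everywhere.
    """
    z = np.asarray(elevations, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise ShapeError("elevation grid must be 2-D and non-empty")
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    zp = np.pad(z, 1, mode="symmetric")
    # Horn 1981 weights: diagonal 1, cardinal 2.
    dzdx = (
        (zp[:-2, 2:] + 2.0 * zp[1:-1, 2:] + zp[2:, 2:])
        - (zp[:-2, :-2] + 2.0 * zp[1:-1, :-2] + zp[2:, :-2])
    ) / (8.0 * cell_size)
    dzdy = (
        (zp[2:, :-2] + 2.0 * zp[2:, 1:-1] + zp[2:, 2:])
        - (zp[:-2, :-2] + 2.0 * zp[:-2, 1:-1] + zp[:-2, 2:])
    ) / (8.0 * cell_size)
    return np.hypot(dzdx, dzdy)
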