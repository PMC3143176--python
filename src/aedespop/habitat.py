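"""Houses, water-holding containers, and the replicated simulation grid.

The spatial unit of the model is a house cell on a rectangular lattice; each
house holds a surveyed inventory of water-holding containers (the larval
development sites).  A field-surveyed block of houses can be replicated
``n_copies`` times into a larger grid: every copy keeps each house's container
inventory verbatim but re-randomizes house placement within its block, so a
given house id occurs once per block with different neighbors each time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTAINER_TYPES",
    "ContainerSpec",
    "House",
    "SimulationGrid",
    "build_replicated_grid",
    "manhattan_distance",
    "read_survey",
    "write_survey",
]

#: The 14 container categories, in decreasing order of field pupal productivity.
CONTAINER_TYPES = (
    "plastic",
    "medium storage",
    "large tanks",
    "tires",
    "non-traditional",
    "cooking",
    "miscellaneous",
    "flower pots",
    "cans",
    "bath",
    "bottles",
    "natural",
    "wells",
    "pet",
)

LOCATIONS = ("inside", "outside")
FILL_METHODS = ("manual", "passive-rain", "assisted-rain")

#: Index of the normalization reference type (food coefficient alpha == 1).
REFERENCE_TYPE = "large tanks"
#: Location with food coefficient beta == 1.
REFERENCE_LOCATION = "outside"


@dataclass(frozen=True)
class ContainerSpec:
    """Static description of one larval development site."""

    container_id: str
    house_id: str
    type_name: str              # one of CONTAINER_TYPES
    location: str               # "inside" | "outside"
    sun_exposure: float         # fraction of day in direct sun, 0-1
    has_lid: bool
    fill_method: str            # "manual" | "passive-rain" | "assisted-rain"
    volume_l: float

    def __post_init__(self) -> None:
        if self.type_name not in CONTAINER_TYPES:
            raise ValueError(f"unknown container type {self.type_name!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.fill_method not in FILL_METHODS:
            raise ValueError(f"unknown fill method {self.fill_method!r}")
        if not self.volume_l > 0:
            raise ValueError("container volume must be positive")
        if not 0.0 <= self.sun_exposure <= 1.0:
            raise ValueError("sun_exposure must be in [0, 1]")

    @property
    def type_index(self) -> int:
        return CONTAINER_TYPES.index(self.type_name)


@dataclass(frozen=True)
class House:
    """One house cell: stable identity, grid position, container inventory."""

    house_id: str
    row: int
    col: int
    containers: tuple[ContainerSpec, ...] = ()

    def moved_to(self, row: int, col: int) -> "House":
        return replace(self, row=row, col=col)


@dataclass(frozen=True)
class SimulationGrid:
    """A rectangle of houses made of ``n_copies`` tiled blocks."""

    houses: tuple[House, ...]
    block_rows: int
    block_cols: int
    n_copies: int
    tiling: tuple[int, int]  # (blocks down, blocks across)

    def __post_init__(self) -> None:
        if len(self.houses) != self.block_rows * self.block_cols * self.n_copies:
            raise ValueError("house count does not match block size x n_copies")
        coords = {(h.row, h.col) for h in self.houses}
        if len(coords) != len(self.houses):
            raise ValueError("duplicate grid coordinates")

    @property
    def n_rows(self) -> int:
        return self.block_rows * self.tiling[0]

    @property
    def n_cols(self) -> int:
        return self.block_cols * self.tiling[1]

    @property
    def n_houses(self) -> int:
        return len(self.houses)

    @property
    def n_containers(self) -> int:
        return sum(len(h.containers) for h in self.houses)

    def positions(self) -> np.ndarray:
        """(N, 2) array of (row, col) per house, in house order."""
        return np.array([(h.row, h.col) for h in self.houses], dtype=int)


def manhattan_distance(a: House, b: House) -> int:
    """Number of horizontal/vertical grid steps separating two houses."""
    return abs(a.row - b.row) + abs(a.col - b.col)


def _default_tiling(n_copies: int) -> tuple[int, int]:
    # most compact rectangle of blocks (minimizes boundary perimeter)
    best = (1, n_copies)
    for down in range(1, n_copies + 1):
        if n_copies % down == 0:
            across = n_copies // down
            if abs(down - across) < abs(best[0] - best[1]):
                best = (down, across)
    return best


def build_replicated_grid(
    subset: Sequence[House],
    block_rows: int,
    block_cols: int,
    n_copies: int,
    seed: int,
    tiling: tuple[int, int] | None = None,
) -> SimulationGrid:
    """Tile ``n_copies`` copies of a surveyed block into one rectangle.

    Within each copy, house-to-cell assignment is an independent seeded
    uniform permutation; container inventories per house id are preserved
    verbatim.  ``tiling`` overrides the block arrangement (defaults to the
    most compact rectangle, e.g. 2x2 for four copies).
    """
    if len(subset) != block_rows * block_cols:
        raise ValueError(
            f"subset has {len(subset)} houses, expected {block_rows * block_cols}"
        )
    if tiling is None:
        tiling = _default_tiling(n_copies)
    if tiling[0] * tiling[1] != n_copies:
        raise ValueError("tiling does not hold n_copies blocks")

    rng = np.random.default_rng(seed)
    cells = [(r, c) for r in range(block_rows) for c in range(block_cols)]
    houses: list[House] = []
    for copy_idx in range(n_copies):
        br, bc = divmod(copy_idx, tiling[1])
        order = rng.permutation(len(subset))
        for cell_idx, house_idx in enumerate(order):
            r, c = cells[cell_idx]
            h = subset[house_idx]
            houses.append(h.moved_to(br * block_rows + r, bc * block_cols + c))
    return SimulationGrid(
        houses=tuple(houses),
        block_rows=block_rows,
        block_cols=block_cols,
        n_copies=n_copies,
        tiling=tiling,
    )


def single_block_grid(subset: Sequence[House], block_rows: int, block_cols: int,
                      seed: int = 0) -> SimulationGrid:
    """Grid-composition option B: the surveyed block simulated once."""
    return build_replicated_grid(subset, block_rows, block_cols, 1, seed)


# ---------------------------------------------------------------------------
# survey file dialect: container_id,house_id,row,col,type,location,sun,lid,
#                      fill,volume_l

def write_survey(houses: Iterable[House], path) -> None:
    rows = []
    for h in houses:
        for c in h.containers:
            rows.append(
                {
                    "container_id": c.container_id,
                    "house_id": h.house_id,
                    "row": h.row,
                    "col": h.col,
                    "type": c.type_name,
                    "location": c.location,
                    "sun": c.sun_exposure,
                    "lid": int(c.has_lid),
                    "fill": c.fill_method,
                    "volume_l": c.volume_l,
                }
            )
        if not h.containers:
            rows.append(
                {
                    "container_id": "",
                    "house_id": h.house_id,
                    "row": h.row,
                    "col": h.col,
                    "type": "",
                    "location": "",
                    "sun": "",
                    "lid": "",
                    "fill": "",
                    "volume_l": "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_survey(path) -> list[House]:
    """Read a survey CSV back into a list of houses (sorted by house id)."""
    df = pd.read_csv(path, dtype={"container_id": str, "house_id": str})
    houses: dict[str, House] = {}
    for (hid, row, col), grp in df.groupby(["house_id", "row", "col"], sort=True):
        containers = []
        for _, rec in grp.iterrows():
            if not isinstance(rec["container_id"], str) or rec["container_id"] == "":
                continue
            containers.append(
                ContainerSpec(
                    container_id=rec["container_id"],
                    house_id=str(hid),
                    type_name=rec["type"],
                    location=rec["location"],
                    sun_exposure=float(rec["sun"]),
                    has_lid=bool(int(rec["lid"])),
                    fill_method=rec["fill"],
                    volume_l=float(rec["volume_l"]),
                )
            )
        houses[str(hid)] = House(
            house_id=str(hid), row=int(row), col=int(col),
            containers=tuple(containers),
        )
    return [houses[k] for k in sorted(houses)]
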