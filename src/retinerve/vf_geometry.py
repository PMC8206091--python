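"""Geometry of the 24-2 Humphrey visual-field chart.

The 24-2 test pattern probes 54 locations on a 6-degree lattice; the two
points straddling the physiologic blind spot at (15, +/-3) degrees are
conventionally excluded, leaving 52. This module builds that grid (right-eye
convention, temporal positive in x, superior positive in y), splits it into
chart hemifields, orders each hemifield by distance from the blind spot into
the seven "recursive passes" used by the network (slice sizes 5,4,4,4,4,4,1),
attaches a Garway-Heath-style sector label to every point, and provides the
Mean Deviation (MD) weighting mask plus disease-severity staging of MD.

Severity conventions (MD in dB, more negative = worse):

* stages   -- early/no disease (MD > -6), moderate (-12 < MD <= -6),
              advanced (MD <= -12);
* intervals -- the four class-balance bins used by the sample-weighting loss:
              (> -6], (-6, -16], (-16, -26], (<= -26) with the boundary value
              falling into the worse bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "VFLocation",
    "VFGrid",
    "PASS_SIZES",
    "SECTORS",
    "build_grid",
    "assign_passes",
    "location_distance",
    "stage_of",
    "interval_of",
    "sector_of",
    "default_sector_table",
    "md_from_td",
    "uniform_md_mask",
]

#: Output-slice sizes of the seven recursive passes within one hemifield.
PASS_SIZES: Tuple[int, ...] = (5, 4, 4, 4, 4, 4, 1)

#: The six visual-field sectors reported for sectoral averages.
SECTORS: Tuple[str, ...] = (
    "central",
    "temporal",
    "inferior",
    "inferior_nasal",
    "superior",
    "superior_nasal",
)

#: Excluded blind-spot chart locations (right-eye convention).
BLIND_SPOT: Tuple[Tuple[int, int], ...] = ((15, 3), (15, -3))

#: Row layout of the full (pre-exclusion) 24-2 pattern: y -> tuple of x.
_ROWS: Dict[int, Tuple[int, ...]] = {}
for _y, _xs in (
    (21, (-9, -3, 3, 9)),
    (15, (-15, -9, -3, 3, 9, 15)),
    (9, (-21, -15, -9, -3, 3, 9, 15, 21)),
    (3, (-27, -21, -15, -9, -3, 3, 9, 15, 21)),
):
    _ROWS[_y] = _xs
    _ROWS[-_y] = _xs

#: Grid spacing in degrees; one grid step defines the unit of d_j.
GRID_STEP_DEG = 6.0


@dataclass(frozen=True)
class VFLocation:
    """One tested location of the 24-2 chart.

    ``pass_t``/``slot`` give the recursive pass (1..7) that emits this point
    and its position within that pass's output slice; ``d_j`` is the distance
    from fixation in grid-step units (degrees / 6).
    """

    x_deg: int
    y_deg: int
    index_j: int = -1
    hemifield: str = ""
    pass_t: int = 0
    slot: int = -1
    sector: str = ""

    @property
    def d_j(self) -> float:
        return math.hypot(self.x_deg, self.y_deg) / GRID_STEP_DEG


def location_distance(loc: "VFLocation | Tuple[float, float]") -> float:
    """Center distance of a chart location in grid-step units (deg / 6)."""
    if isinstance(loc, VFLocation):
        return loc.d_j
    x, y = loc
    return math.hypot(x, y) / GRID_STEP_DEG


class VFGrid:
    """The 52-location 24-2 grid with hemifield and pass structure.

    Canonical ordering: the inferior-chart hemifield block (26 points) comes
    first, then the superior-chart block, each internally ordered by
    ``(pass_t, slot)``.  This matches the order in which the sub-networks emit
    their estimates, so a 52-vector in canonical order is simply the
    concatenation of the two emission sequences.
    """

    def __init__(self, locations: Sequence[VFLocation]):
        if len(locations) != 52:
            raise ValueError(f"expected 52 locations, got {len(locations)}")
        self.locations: List[VFLocation] = list(locations)
        self._by_coord = {(l.x_deg, l.y_deg): l for l in self.locations}
        for hemi in ("inferior_chart", "superior_chart"):
            if sum(1 for l in self.locations if l.hemifield == hemi) != 26:
                raise ValueError(f"hemifield {hemi!r} does not hold 26 points")

    def __len__(self) -> int:
        return len(self.locations)

    def __iter__(self):
        return iter(self.locations)

    def __getitem__(self, index_j: int) -> VFLocation:
        return self.locations[index_j]

    def at(self, x_deg: int, y_deg: int) -> VFLocation:
        return self._by_coord[(x_deg, y_deg)]

    def hemifield(self, name: str) -> List[VFLocation]:
        """The 26 locations of one chart hemifield, in canonical order."""
        return [l for l in self.locations if l.hemifield == name]

    @property
    def distances(self) -> np.ndarray:
        """d_j for all 52 locations, canonical order."""
        return np.array([l.d_j for l in self.locations])

    def sector_indices(self) -> Dict[str, np.ndarray]:
        """Canonical indices of each sector's member locations."""
        out: Dict[str, List[int]] = {s: [] for s in SECTORS}
        for l in self.locations:
            out[l.sector].append(l.index_j)
        return {s: np.array(v, dtype=int) for s, v in out.items()}


def _full_pattern() -> List[Tuple[int, int]]:
    """All 54 chart coordinates of the 24-2 pattern, before exclusion."""
    return [(x, y) for y in sorted(_ROWS) for x in _ROWS[y]]


def build_grid(sector_table: Optional[Mapping[Tuple[int, int], str]] = None) -> VFGrid:
    """Construct the canonical 52-location 24-2 grid.

    Builds the 54-point pattern, removes the two blind-spot points, splits
    into chart hemifields, assigns recursive passes and sectors, and returns
    the grid in canonical order.
    """
    pts = [p for p in _full_pattern() if p not in BLIND_SPOT]
    assert len(pts) == 52
    locs = [
        VFLocation(x, y, hemifield="superior_chart" if y > 0 else "inferior_chart")
        for x, y in pts
    ]
    return assign_passes(locs, sector_table=sector_table)


def _pass_order_key(anchor: Tuple[int, int]):
    ax, ay = anchor

    def key(loc: VFLocation):
        dist = math.hypot(loc.x_deg - ax, loc.y_deg - ay)
        # ties: larger x first, then smaller |y| first
        return (dist, -loc.x_deg, abs(loc.y_deg))

    return key


def assign_passes(
    locations: Iterable[VFLocation],
    sector_table: Optional[Mapping[Tuple[int, int], str]] = None,
) -> VFGrid:
    """Assign (pass_t, slot) within each hemifield and finalize the grid.

    Within a hemifield the 26 points are sorted by Euclidean distance from
    that hemifield's blind-spot anchor ((15, 3) superior chart, (15, -3)
    inferior chart) and carved into consecutive slices of sizes
    ``PASS_SIZES``; the t-th slice is emitted by the t-th recursive pass.
    """
    locs = list(locations)
    table = dict(sector_table) if sector_table is not None else default_sector_table()
    by_hemi: Dict[str, List[VFLocation]] = {"inferior_chart": [], "superior_chart": []}
    for l in locs:
        by_hemi[l.hemifield].append(l)
    for hemi, members in by_hemi.items():
        if len(members) != 26:
            raise ValueError(f"hemifield {hemi!r} has {len(members)} points, expected 26")

    ordered: List[VFLocation] = []
    for hemi in ("inferior_chart", "superior_chart"):  # canonical block order
        anchor = (15, 3) if hemi == "superior_chart" else (15, -3)
        members = sorted(by_hemi[hemi], key=_pass_order_key(anchor))
        i = 0
        for t, size in enumerate(PASS_SIZES, start=1):
            for slot in range(size):
                loc = members[i]
                ordered.append(
                    replace(
                        loc,
                        index_j=len(ordered),
                        pass_t=t,
                        slot=slot,
                        sector=table[(loc.x_deg, loc.y_deg)],
                    )
                )
                i += 1
    return VFGrid(ordered)


# ---------------------------------------------------------------------------
# Severity staging and MD intervals
# ---------------------------------------------------------------------------

def stage_of(md: float) -> str:
    """Disease stage from MD: early_or_none / moderate / advanced."""
    if not np.isfinite(md):
        raise ValueError(f"MD must be finite, got {md!r}")
    if md > -6:
        return "early_or_none"
    if md > -12:
        return "moderate"
    return "advanced"


def interval_of(md: float) -> int:
    """Class-balance interval 1..4 of an MD value.

    1: MD > -6;  2: -6 >= MD > -16;  3: -16 >= MD > -26;  4: -26 > MD is
    read inclusively on the worse side, i.e. MD <= -26.
    """
    if not np.isfinite(md):
        raise ValueError(f"MD must be finite, got {md!r}")
    if md > -6:
        return 1
    if md > -16:
        return 2
    if md > -26:
        return 3
    return 4


# ---------------------------------------------------------------------------
# Sectors
# ---------------------------------------------------------------------------

def default_sector_table() -> Dict[Tuple[int, int], str]:
    """Garway-Heath-style sector assignment of the 52 chart locations.

    The published optic-disc/visual-field correspondence map is not
    reproduced numerically here; this default follows its qualitative layout
    geometrically (right-eye chart): the innermost ring plus the two points
    just temporal of fixation form the papillomacular *central* sector; the
    wedge around the blind spot is *temporal*; the nasal field (x <= -9)
    splits into *superior_nasal* / *inferior_nasal* by hemifield; the
    remaining arcuate points form *superior* / *inferior*. The table is a
    plain mapping and can be replaced wholesale by a user-supplied one.
    """
    table: Dict[Tuple[int, int], str] = {}
    for x, y in _full_pattern():
        if (x, y) in BLIND_SPOT:
            continue
        if abs(y) == 3 and -3 <= x <= 9:
            table[(x, y)] = "central"
        elif x >= 15:
            table[(x, y)] = "temporal"
        elif x <= -9:
            table[(x, y)] = "superior_nasal" if y > 0 else "inferior_nasal"
        else:
            table[(x, y)] = "superior" if y > 0 else "inferior"
    return table


def load_sector_table(path: str) -> Dict[Tuple[int, int], str]:
    """Load a sector table from YAML/JSON keyed by ``"(x,y)"`` chart degrees."""
    import yaml

    with open(path) as f:
        raw = yaml.safe_load(f)
    table: Dict[Tuple[int, int], str] = {}
    for key, sector in raw.items():
        x, y = (int(v) for v in str(key).strip("() ").split(","))
        if sector not in SECTORS:
            raise ValueError(f"unknown sector {sector!r} for location {key}")
        table[(x, y)] = sector
    return table


def save_sector_table(table: Mapping[Tuple[int, int], str], path: str) -> None:
    import yaml

    with open(path, "w") as f:
        yaml.safe_dump({f"({x},{y})": s for (x, y), s in sorted(table.items())}, f)


def sector_of(
    loc: VFLocation,
    table: Optional[Mapping[Tuple[int, int], str]] = None,
) -> str:
    """Sector label of a chart location under the given (or default) table."""
    table = table if table is not None else default_sector_table()
    key = (loc.x_deg, loc.y_deg)
    if key not in table:
        raise KeyError(f"location {key} not in sector table")
    return table[key]


# ---------------------------------------------------------------------------
# Mean Deviation
# ---------------------------------------------------------------------------

def uniform_md_mask() -> np.ndarray:
    """The default MD weight mask: uniform 1/52 over all locations."""
    return np.full(52, 1.0 / 52.0)


def md_from_td(td: np.ndarray, mask: Optional[np.ndarray] = None) -> "float | np.ndarray":
    """Mean Deviation as a weighted average of the 52 TD values.

    ``td`` may be a single 52-vector or an (N, 52) batch.  The mask must be
    non-negative and sum to one (instrument-specific eccentricity weights are
    proprietary; the uniform mask is the default and the simulator's truth).
    """
    td = np.asarray(td, dtype=float)
    mask = uniform_md_mask() if mask is None else np.asarray(mask, dtype=float)
    if mask.shape != (52,):
        raise ValueError(f"mask must have shape (52,), got {mask.shape}")
    if np.any(mask < 0) or not math.isclose(float(mask.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("mask weights must be non-negative and sum to 1")
    if td.shape[-1] != 52:
        raise ValueError(f"td must have trailing length 52, got {td.shape}")
    out = td @ mask
    return float(out) if out.ndim == 0 else out
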