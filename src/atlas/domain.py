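"""Study domain: a rectangular planar-km extent tiled by district polygons.

All coordinates in the package are planar kilometres (a local projected
frame), so Euclidean distances are exact and no CRS machinery is needed.
Districts stand in for administrative reporting units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from shapely.geometry import Polygon, box
from shapely.ops import unary_union

_AREA_TOL = 1e-9  # km^2 tolerance for the tiling invariant


@dataclass(frozen=True)
class StudyDomain:
    """Rectangular study extent partitioned into districts.

    Parameters
    ----------
    extent
        ``(xmin, ymin, xmax, ymax)`` in km.
    districts
        List of ``(district_id, polygon)`` pairs. The polygons must tile
        the extent (no gaps or overlaps beyond ``1e-9`` km²).
    crs_note
        Free-text tag recording that coordinates are planar km.
    """

    extent: tuple[float, float, float, float]
    districts: list[tuple[int, Polygon]] = field(default_factory=list)
    crs_note: str = "planar-km (local projection)"

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"extent must have positive width and height: {self.extent}")
        if self.districts:
            total = sum(p.area for _, p in self.districts)
            extent_area = (xmax - xmin) * (ymax - ymin)
            union = unary_union([p for _, p in self.districts])
            if abs(total - extent_area) > _AREA_TOL or abs(union.area - extent_area) > _AREA_TOL:
                raise ValueError(
                    "districts do not tile the extent: "
                    f"sum of areas {total}, union area {union.area}, extent area {extent_area}"
                )

    @property
    def width(self) -> float:
        return self.extent[2] - self.extent[0]

    @property
    def height(self) -> float:
        return self.extent[3] - self.extent[1]

    @property
    def area(self) -> float:
        return self.width * self.height

    def district_ids(self) -> list[int]:
        return [i for i, _ in self.districts]


def generate_domain(n_x: int, n_y: int, cell_km: float) -> StudyDomain:
    """Build a rectangular domain tiled by ``n_x × n_y`` square districts.

    District ids run row-major from 0, starting at the south-west corner.

    Parameters
    ----------
    n_x, n_y
        Number of districts along x and y. Must be >= 1.
    cell_km
        Side length of each (square) district in km. Must be > 0.
    """
    if n_x < 1 or n_y < 1:
        raise ValueError(f"n_x and n_y must be >= 1, got {n_x}, {n_y}")
    if cell_km <= 0:
        raise ValueError(f"cell_km must be > 0, got {cell_km}")
    districts = []
    for j in range(n_y):
        for i in range(n_x):
            did = j * n_x + i
            poly = box(i * cell_km, j * cell_km, (i + 1) * cell_km, (j + 1) * cell_km)
            districts.append((did, poly))
    extent = (0.0, 0.0, n_x * cell_km, n_y * cell_km)
    return StudyDomain(extent=extent, districts=districts)
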