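"""Parameterised five-region growth-plate domain and its quadrilateral mesh.

The analysis domain is an 800 um square cross-section of the physis stacked,
bottom to top, as: metaphyseal trabecular bone, hypertrophic cartilage,
proliferative cartilage, reserve cartilage, epiphyseal trabecular bone.  The
two bone caps share whatever thickness the cartilage leaves over.  Growth is
along +y; y = 0 at the metaphyseal boundary.

The mesh is a structured grid of axis-aligned 4-node quadrilaterals,
parameterised by the cellularity: laterally, 20 chondrocyte columns of
40 um tile the full width; vertically, each columnar-zone strip carries one
element row per chondrocyte, so an element contains exactly one cell (cell
anisotropy ratio 1/1 per element).  Growth updates move node rows along y
(Lagrangian stretch of the grown zones); connectivity never changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .parameters import LoadCaseTable, PhysiologicalConstants, Tissue

__all__ = [
    "ZONES",
    "ZONE_TISSUE",
    "ZoneGeometry",
    "MeshRefinement",
    "FEMesh",
    "build_domain",
    "generate_mesh",
    "update_geometry",
]

#: Zone stack, bottom to top.
ZONES: tuple[str, ...] = (
    "metaphyseal_bone",
    "hypertrophic",
    "proliferative",
    "reserve",
    "epiphyseal_bone",
)

#: Material assignment per zone.
ZONE_TISSUE: dict[str, Tissue] = {
    "metaphyseal_bone": Tissue.TRABECULAR_BONE,
    "hypertrophic": Tissue.HYPERTROPHIC,
    "proliferative": Tissue.PROLIFERATIVE,
    "reserve": Tissue.RESERVE,
    "epiphyseal_bone": Tissue.TRABECULAR_BONE,
}

#: Zones whose elements map to chondrocyte columns.
COLUMNAR_ZONES = ("hypertrophic", "proliferative")


@dataclass(frozen=True)
class ZoneGeometry:
    """Thickness stack of the five regions, bottom to top, um."""

    thicknesses: tuple[float, float, float, float, float]
    width: float = 800.0
    growth_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))

    @property
    def total_height(self) -> float:
        return float(sum(self.thicknesses))

    def thickness(self, zone: str) -> float:
        return self.thicknesses[ZONES.index(zone)]


@dataclass(frozen=True)
class MeshRefinement:
    """Row/column counts of the structured grid.

    ``proliferative_rows`` and ``hypertrophic_rows`` default to the cell
    counts of the active load case (one element per chondrocyte);
    non-growing regions only transmit load and get a fixed coarse count.
    """

    proliferative_rows: int
    hypertrophic_rows: int
    reserve_rows: int = 2
    bone_rows: int = 2
    elements_per_column: int = 1

    def rows_for(self, zone: str) -> int:
        return {
            "metaphyseal_bone": self.bone_rows,
            "hypertrophic": self.hypertrophic_rows,
            "proliferative": self.proliferative_rows,
            "reserve": self.reserve_rows,
            "epiphyseal_bone": self.bone_rows,
        }[zone]


@dataclass(frozen=True)
class FEMesh:
    """Structured quadrilateral mesh with tissue/zone/column element maps.

    Nodes are numbered row-major (x fastest); element connectivity is
    counter-clockwise.  ``x_levels``/``y_levels`` are the grid lines;
    ``row_zone`` gives the zone index of each element row, which is what
    geometry updates use to stretch grown zones.
    """

    x_levels: np.ndarray          # (nx+1,) um
    y_levels: np.ndarray          # (ny+1,) um
    row_zone: np.ndarray          # (ny,) zone index 0..4 per element row
    elements_per_column: int

    @property
    def nx(self) -> int:
        return len(self.x_levels) - 1

    @property
    def ny(self) -> int:
        return len(self.y_levels) - 1

    @property
    def nodes(self) -> np.ndarray:
        """(n_nodes, 2) coordinates, um."""
        xx, yy = np.meshgrid(self.x_levels, self.y_levels)
        return np.column_stack([xx.ravel(), yy.ravel()])

    @property
    def elements(self) -> np.ndarray:
        """(n_elems, 4) CCW connectivity."""
        nxp = self.nx + 1
        ix, iy = np.meshgrid(np.arange(self.nx), np.arange(self.ny))
        ix, iy = ix.ravel(), iy.ravel()
        n0 = iy * nxp + ix
        return np.column_stack([n0, n0 + 1, n0 + 1 + nxp, n0 + nxp])

    @property
    def element_zone(self) -> np.ndarray:
        """(n_elems,) zone index per element."""
        return np.repeat(self.row_zone, self.nx)

    @property
    def element_tissue(self) -> list[Tissue]:
        return [ZONE_TISSUE[ZONES[z]] for z in self.element_zone]

    @property
    def element_column(self) -> np.ndarray:
        """(n_elems,) chondrocyte column index, -1 outside columnar zones."""
        ix = np.tile(np.arange(self.nx), self.ny)
        col = ix // self.elements_per_column
        zone_names = np.array(ZONES)[self.element_zone]
        columnar = np.isin(zone_names, COLUMNAR_ZONES)
        return np.where(columnar, col, -1)

    def zone_thickness(self, zone: str) -> float:
        """Current thickness of one zone, um."""
        zi = ZONES.index(zone)
        rows = np.flatnonzero(self.row_zone == zi)
        if len(rows) == 0:
            return 0.0
        return float(self.y_levels[rows[-1] + 1] - self.y_levels[rows[0]])

    @property
    def height(self) -> float:
        return float(self.y_levels[-1] - self.y_levels[0])

    def check_jacobians(self) -> None:
        """Raise if any element is degenerate or inverted."""
        if np.any(np.diff(self.y_levels) <= 0) or np.any(np.diff(self.x_levels) <= 0):
            raise ValueError("mesh has non-positive element Jacobians (inverted/degenerate rows)")


def build_domain(load_case: LoadCaseTable, constants: PhysiologicalConstants) -> ZoneGeometry:
    """Five-region stack for one load case; bone caps split the remainder."""
    reserve, prolif, hyper = load_case.zone_thicknesses
    cartilage = reserve + prolif + hyper
    if cartilage >= constants.domain_side:
        raise ValueError(
            f"cartilage thickness {cartilage} um exceeds the {constants.domain_side} um domain"
        )
    bone = (constants.domain_side - cartilage) / 2.0
    return ZoneGeometry(
        thicknesses=(bone, hyper, prolif, reserve, bone),
        width=constants.domain_side,
    )


def generate_mesh(
    geometry: ZoneGeometry,
    refinement: MeshRefinement,
    columns: int = 20,
    spacing: float = 40.0,
) -> FEMesh:
    """Structured grid over the five-region domain.

    Column strips of width ``spacing`` tile the domain laterally
    (``columns * spacing`` must not exceed the width); each strip is split
    into ``elements_per_column`` element columns.
    """
    if columns * spacing > geometry.width + 1e-9:
        raise ValueError("columns * spacing exceeds the domain width")
    for zone in ZONES:
        if geometry.thickness(zone) <= 0:
            raise ValueError(f"zone {zone!r} has non-positive thickness")

    nx = columns * refinement.elements_per_column
    x_levels = np.linspace(0.0, columns * spacing, nx + 1)

    y_levels = [0.0]
    row_zone: list[int] = []
    for zi, zone in enumerate(ZONES):
        rows = refinement.rows_for(zone)
        t = geometry.thickness(zone)
        y0 = y_levels[-1]
        y_levels.extend(y0 + t * np.arange(1, rows + 1) / rows)
        row_zone.extend([zi] * rows)

    mesh = FEMesh(
        x_levels=x_levels,
        y_levels=np.array(y_levels),
        row_zone=np.array(row_zone, dtype=int),
        elements_per_column=refinement.elements_per_column,
    )
    mesh.check_jacobians()
    return mesh


def update_geometry(mesh: FEMesh, growth_increment: dict[str, float]) -> FEMesh:
    """Stretch grown zones by the given elongations (um) and shift the stack above.

    Rows inside a grown zone are stretched uniformly; everything above a
    grown zone translates upward by the accumulated elongation below it.
    Connectivity and lateral coordinates are untouched.
    """
    inc = np.zeros(len(ZONES))
    for zone, dz in growth_increment.items():
        if zone not in ZONES:
            raise KeyError(f"unknown zone {zone!r}")
        if dz < 0:
            raise ValueError(f"negative growth increment for zone {zone!r}")
        inc[ZONES.index(zone)] = dz

    dy = np.diff(mesh.y_levels)
    new_dy = dy.copy()
    for zi in range(len(ZONES)):
        rows = np.flatnonzero(mesh.row_zone == zi)
        if len(rows) == 0 or inc[zi] == 0.0:
            continue
        thickness = dy[rows].sum()
        new_dy[rows] = dy[rows] * (thickness + inc[zi]) / thickness
    new_levels = np.concatenate([[mesh.y_levels[0]], mesh.y_levels[0] + np.cumsum(new_dy)])

    updated = replace(mesh, y_levels=new_levels)
    updated.check_jacobians()
    return updated
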