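"""Brick-lattice geometry of the bicellular tight-junction (bTJ) strand network.

The paracellular cleft between two epithelial cells is modelled as a 2D
vertical cut through the junction: ``n_strand`` horizontal strands enclose
``n_strand - 1`` rows of small compartments arranged like offset bricks.
Molecules (and ionic current) cross from the basal reservoir below the
bottom strand to the apical compartment above the top strand, passing
through *strand sections* -- the atomic pieces of strand separating two
compartments (or a compartment and a boundary).

The same network serves both barrier models:

* the permeability model treats compartments as well-mixed pools connected
  by stochastic rate constants through broken sections;
* the TER model treats each section as a resistor and solves the mesh
  (loop-current) equations of the resulting planar circuit.

Conventions
-----------
Rows are numbered ``1 .. n_strand - 1`` from the basal side.  Odd rows have
``W = width_compartments`` full-width compartments; even rows have ``W + 1``
compartments whose edge compartments are half-width, so every row spans the
same model width ``W * w_comp``.  Side walls are sealed: there are no
sections on the lateral boundaries and no periodic wrap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: Node labels for the two boundary reservoirs (compartments are >= 0).
BASAL = -1
APICAL = -2

HORIZONTAL = "horizontal"
VERTICAL = "vertical"


@dataclass(frozen=True)
class GeometryParams:
    """Geometric parameters of the strand lattice (SI units, metres).

    Defaults are the standard values used throughout: 100-nm compartments,
    4-nm TJ half-width, 6-nm strand height, 20-nm breaks, 50 compartments
    across, and 200-nm apical/basal compartments.
    """

    n_strand: int = 4
    width_compartments: int = 50
    w_comp: float = 100e-9
    h_comp: float = 100e-9
    w_tj: float = 4e-9
    h_strand: float = 6e-9
    l_break: float = 20e-9
    h_apical: float = 200e-9
    h_basal: float = 200e-9

    def __post_init__(self) -> None:
        if self.n_strand < 2:
            raise ValueError("n_strand must be >= 2 (no compartment rows otherwise)")
        if self.width_compartments < 1:
            raise ValueError("width_compartments must be >= 1")
        for name in ("w_comp", "h_comp", "w_tj", "h_strand", "l_break",
                     "h_apical", "h_basal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        min_section = min(self.w_comp / 2.0, self.h_comp)
        if self.l_break >= min_section:
            raise ValueError(
                "l_break must be smaller than the shortest section "
                f"({min_section:.3g} m)")

    @property
    def w_model(self) -> float:
        """Total model width (m)."""
        return self.width_compartments * self.w_comp


@dataclass(frozen=True)
class StrandSection:
    """One atomic section of strand separating two regions.

    ``u``/``v`` are compartment ids or the boundary labels ``BASAL``/
    ``APICAL``.  ``strand`` is the 1-based index of the horizontal strand a
    horizontal section belongs to (``None`` for vertical connector
    sections); ``row`` is the compartment row a vertical section sits in.
    A section is atomic: it holds at most one break and has no internal
    spatial coordinate.
    """

    id: int
    u: int
    v: int
    length: float
    orientation: str
    strand: int | None = None
    row: int | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("section length must be > 0")


class StrandNetwork:
    """Built brick lattice: compartments, sections and mesh loops.

    Attributes
    ----------
    geom : GeometryParams
    comp_row : (N,) int array, row index (1-based from basal) per compartment
    comp_x0, comp_x1 : (N,) float arrays, horizontal extent in units of w_comp
    areas : (N,) float array, compartment areas (m^2)
    sections : list[StrandSection]
    loops : list[list[int]]
        Inner mesh loops as lists of section ids (the bounded faces of the
        planar conduction graph).
    outer_loop : list[int]
        Section ids on the outer mesh loop; the loop closes through the
        virtual voltage-source branch (not a section).
    """

    def __init__(self, geom: GeometryParams):
        self.geom = geom
        self._build()

    # -- construction ---------------------------------------------------

    def _row_bounds(self, r: int) -> list[float]:
        """Compartment boundaries of row r in units of w_comp."""
        W = self.geom.width_compartments
        if r % 2 == 1:  # W full-width compartments
            return [float(k) for k in range(W + 1)]
        # W + 1 compartments, half-width at the edges
        return [0.0] + [k + 0.5 for k in range(W)] + [float(W)]

    def _build(self) -> None:
        g = self.geom
        W = g.width_compartments
        n_rows = g.n_strand - 1

        comp_row: list[int] = []
        comp_x0: list[float] = []
        comp_x1: list[float] = []
        self._rows: list[list[int]] = []  # compartment ids per row
        for r in range(1, n_rows + 1):
            bounds = self._row_bounds(r)
            ids = []
            for x0, x1 in zip(bounds[:-1], bounds[1:]):
                ids.append(len(comp_row))
                comp_row.append(r)
                comp_x0.append(x0)
                comp_x1.append(x1)
            self._rows.append(ids)
        self.comp_row = np.asarray(comp_row, dtype=np.int64)
        self.comp_x0 = np.asarray(comp_x0, dtype=float)
        self.comp_x1 = np.asarray(comp_x1, dtype=float)
        self.n_compartments = len(comp_row)
        self.areas = (self.comp_x1 - self.comp_x0) * g.w_comp * g.h_comp

        def comp_covering(row_ids: list[int], x_mid: float) -> int:
            for cid in row_ids:
                if self.comp_x0[cid] <= x_mid <= self.comp_x1[cid]:
                    return cid
            raise RuntimeError("no compartment covers interval")  # pragma: no cover

        sections: list[StrandSection] = []
        self._edge: dict[tuple[int, int], int] = {}

        def add_section(u: int, v: int, length: float, orientation: str,
                        strand: int | None = None, row: int | None = None) -> int:
            sid = len(sections)
            sections.append(StrandSection(sid, u, v, length, orientation,
                                          strand, row))
            self._edge[(u, v)] = sid
            self._edge[(v, u)] = sid
            return sid

        # bottom strand (1): one section per row-1 compartment
        for cid in self._rows[0]:
            width = (self.comp_x1[cid] - self.comp_x0[cid]) * g.w_comp
            add_section(BASAL, cid, width, HORIZONTAL, strand=1)
        # interior strands s = 2 .. n_strand - 1 between rows s-1 and s:
        # 2W half-length sections, one per overlap interface
        for s in range(2, g.n_strand):
            lower, upper = self._rows[s - 2], self._rows[s - 1]
            for k in range(2 * W):
                x_mid = (k + 0.5) / 2.0
                cl = comp_covering(lower, x_mid)
                cu = comp_covering(upper, x_mid)
                add_section(cl, cu, g.w_comp / 2.0, HORIZONTAL, strand=s)
        # top strand (n_strand): one section per top-row compartment
        for cid in self._rows[-1]:
            width = (self.comp_x1[cid] - self.comp_x0[cid]) * g.w_comp
            add_section(cid, APICAL, width, HORIZONTAL, strand=g.n_strand)
        # vertical sections between same-row neighbours
        for r, ids in enumerate(self._rows, start=1):
            for a, b in zip(ids[:-1], ids[1:]):
                add_section(a, b, g.h_comp, VERTICAL, row=r)

        self.sections = sections
        self.section_u = np.asarray([s.u for s in sections], dtype=np.int64)
        self.section_v = np.asarray([s.v for s in sections], dtype=np.int64)
        self.section_lengths = np.asarray([s.length for s in sections])

        self._build_loops()

    def _build_loops(self) -> None:
        """Enumerate the bounded faces of the planar conduction graph.

        Faces come in three families: triangles [basal, c_k, c_k+1] under
        the bottom strand, triangles spanning each vertical section and the
        single opposite-row compartment covering it, and triangles
        [c_k, c_k+1, apical] above the top strand.
        """
        g = self.geom
        loop_nodes: list[list[int]] = []

        first = self._rows[0]
        for a, b in zip(first[:-1], first[1:]):
            loop_nodes.append([BASAL, a, b])

        for r in range(len(self._rows) - 1):
            lower, upper = self._rows[r], self._rows[r + 1]
            # vertical sections in the lower row -> triangle with upper comp
            for a, b in zip(lower[:-1], lower[1:]):
                x = self.comp_x1[a]
                d = next(c for c in upper
                         if self.comp_x0[c] < x < self.comp_x1[c])
                loop_nodes.append([a, b, d])
            # vertical sections in the upper row -> triangle with lower comp
            for a, b in zip(upper[:-1], upper[1:]):
                x = self.comp_x1[a]
                c = next(c for c in lower
                         if self.comp_x0[c] < x < self.comp_x1[c])
                loop_nodes.append([a, b, c])

        last = self._rows[-1]
        for a, b in zip(last[:-1], last[1:]):
            loop_nodes.append([a, b, APICAL])

        self.loop_nodes = loop_nodes
        self.loops = [[self._edge[(cyc[i], cyc[(i + 1) % len(cyc)])]
                       for i in range(len(cyc))] for cyc in loop_nodes]

        # outer mesh: basal -> leftmost column -> apical, closed by the
        # virtual source branch apical -> basal
        path = [BASAL] + [ids[0] for ids in self._rows] + [APICAL]
        self.outer_loop_nodes = path
        self.outer_loop = [self._edge[(path[i], path[i + 1])]
                           for i in range(len(path) - 1)]

    # -- queries ---------------------------------------------------------

    @property
    def w_model(self) -> float:
        return self.geom.w_model

    def section_id(self, u: int, v: int) -> int:
        return self._edge[(u, v)]

    def strand_section_ids(self, strand: int) -> list[int]:
        """Ids of the horizontal sections making up one strand (1-based)."""
        return [s.id for s in self.sections if s.strand == strand]

    def row_compartments(self, row: int) -> list[int]:
        return list(self._rows[row - 1])

    @property
    def n_rows(self) -> int:
        return len(self._rows)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "geometry": {
                "n_strand": self.geom.n_strand,
                "width_compartments": self.geom.width_compartments,
                "w_comp": self.geom.w_comp,
                "h_comp": self.geom.h_comp,
                "w_tj": self.geom.w_tj,
                "h_strand": self.geom.h_strand,
                "l_break": self.geom.l_break,
                "h_apical": self.geom.h_apical,
                "h_basal": self.geom.h_basal,
            },
            "compartments": [
                {"id": int(i), "row": int(self.comp_row[i]),
                 "area": float(self.areas[i])}
                for i in range(self.n_compartments)
            ],
            "sections": [
                {"id": s.id, "u": s.u, "v": s.v, "length": s.length,
                 "orientation": s.orientation}
                for s in self.sections
            ],
            "loops": self.loops,
            "outer_loop": self.outer_loop,
            "w_model": self.w_model,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def build_network(geom: GeometryParams) -> StrandNetwork:
    """Build the brick-lattice strand network for the given geometry."""
    return StrandNetwork(geom)


def section_length(section: StrandSection) -> float:
    """Length of a strand section (m)."""
    return section.length


def from_json(text: str) -> StrandNetwork:
    """Rebuild a network from its JSON serialization (geometry round-trip)."""
    d = json.loads(text)
    return build_network(GeometryParams(**d["geometry"]))
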