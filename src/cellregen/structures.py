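"""Cell structures on the 2D integer lattice.

A structure is a sparse, finite set of occupied lattice nodes, each carrying
a role label.  Before amputation every cell is ``original``; amputation
relabels cells as ``control`` (remaining) or ``removed``, and the engine
later adds ``new`` cells.  The *blastema* is the set of control cells that
touch (8-neighbourhood) at least one removed cell; it is frozen at
amputation time because it is the seeding front for regrowth.

Distances are Euclidean on unit-spaced node coordinates, so side neighbours
sit at distance 1 and diagonal neighbours at sqrt(2).
"""

from __future__ import annotations

import csv
import io
import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Iterator, Union

from .errors import (
    EmptyStructureError,
    InvalidAmputationError,
    InvalidArgumentError,
)

Node = tuple[int, int]

__all__ = [
    "Node",
    "Role",
    "CellStructure",
    "AmputationMask",
    "neighbors8",
    "make_rectangle",
    "make_ellipse",
    "make_glyph",
    "amputate",
    "GLYPH_IDS",
]


class Role(str, Enum):
    ORIGINAL = "original"
    CONTROL = "control"
    NEW = "new"
    REMOVED = "removed"


#: A mask is either an explicit node collection or a predicate over nodes.
AmputationMask = Union[Iterable[Node], Callable[[Node], bool]]

_OFFSETS8 = (
    (-1, -1), (0, -1), (1, -1),
    (-1, 0), (1, 0),
    (-1, 1), (0, 1), (1, 1),
)


def neighbors8(node: Node) -> frozenset[Node]:
    """The Moore neighbourhood: 4 side + 4 diagonal neighbours."""
    x, y = node
    return frozenset((x + dx, y + dy) for dx, dy in _OFFSETS8)


@dataclass
class CellStructure:
    """A finite set of occupied lattice nodes with per-node role labels.

    Parameters
    ----------
    roles
        Mapping from node to role.  Nodes are ``(x, y)`` integer pairs.
    name
        Optional identifier used in serialized form.
    blastema
        Control cells adjacent to removed cells; assigned by :func:`amputate`.
    """

    roles: dict[Node, Role]
    name: str = ""
    blastema: frozenset[Node] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.roles:
            raise EmptyStructureError("a cell structure must contain at least one node")
        for node in self.roles:
            x, y = node
            if not (isinstance(x, int) and isinstance(y, int)):
                raise InvalidArgumentError(f"non-integer node coordinates: {node!r}")

    # -- role views ---------------------------------------------------------

    @property
    def nodes(self) -> frozenset[Node]:
        return frozenset(self.roles)

    def nodes_with_role(self, role: Role) -> frozenset[Node]:
        return frozenset(n for n, r in self.roles.items() if r is role)

    @property
    def control(self) -> frozenset[Node]:
        return self.nodes_with_role(Role.CONTROL)

    @property
    def removed(self) -> frozenset[Node]:
        return self.nodes_with_role(Role.REMOVED)

    @property
    def new(self) -> frozenset[Node]:
        return self.nodes_with_role(Role.NEW)

    @property
    def original_nodes(self) -> frozenset[Node]:
        """Nodes of the pre-amputation structure (everything but new cells)."""
        return frozenset(n for n, r in self.roles.items() if r is not Role.NEW)

    @property
    def occupied(self) -> frozenset[Node]:
        """Nodes currently holding a living cell (removed sites are empty)."""
        return frozenset(n for n, r in self.roles.items() if r is not Role.REMOVED)

    @property
    def is_amputated(self) -> bool:
        return any(r is not Role.ORIGINAL for r in self.roles.values())

    def __len__(self) -> int:
        return len(self.roles)

    def __iter__(self) -> Iterator[Node]:
        return iter(self.roles)

    def __contains__(self, node: object) -> bool:
        return node in self.roles

    # -- mutation used by the engine ---------------------------------------

    def add_new(self, node: Node) -> None:
        """Place a new cell at an empty or removed lattice site."""
        if self.roles.get(node) not in (None, Role.REMOVED):
            raise InvalidArgumentError(f"node {node} is already occupied")
        self.roles[node] = Role.NEW

    def copy(self) -> "CellStructure":
        return CellStructure(dict(self.roles), self.name, self.blastema)

    # -- geometry -----------------------------------------------------------

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(xmin, ymin, xmax, ymax) over all nodes, inclusive."""
        xs = [n[0] for n in self.roles]
        ys = [n[1] for n in self.roles]
        return min(xs), min(ys), max(xs), max(ys)

    # -- serialization ------------------------------------------------------

    def to_csv(self) -> str:
        """`x,y,role` CSV text, nodes in (y, x) lexicographic order, LF endings."""
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["x", "y", "role"])
        for x, y in sorted(self.roles, key=lambda n: (n[1], n[0])):
            writer.writerow([x, y, self.roles[(x, y)].value])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str, name: str = "") -> "CellStructure":
        reader = csv.reader(io.StringIO(text))
        header = next(reader)
        if header != ["x", "y", "role"]:
            raise InvalidArgumentError(f"bad structure CSV header: {header!r}")
        roles: dict[Node, Role] = {}
        for row in reader:
            if not row:
                continue
            x, y, role = int(row[0]), int(row[1]), Role(row[2])
            roles[(x, y)] = role
        structure = cls(roles, name=name)
        if structure.is_amputated:
            structure.blastema = _blastema(structure.control, structure.removed)
        return structure

    def to_json(self) -> str:
        nodes = [
            [x, y, self.roles[(x, y)].value]
            for x, y in sorted(self.roles, key=lambda n: (n[1], n[0]))
        ]
        return json.dumps({"name": self.name, "nodes": nodes})

    @classmethod
    def from_json(cls, text: str) -> "CellStructure":
        doc = json.loads(text)
        roles = {(int(x), int(y)): Role(role) for x, y, role in doc["nodes"]}
        structure = cls(roles, name=doc.get("name", ""))
        if structure.is_amputated:
            structure.blastema = _blastema(structure.control, structure.removed)
        return structure


# -- shape generators -------------------------------------------------------


def make_rectangle(width: int, height: int, origin: Node = (0, 0)) -> CellStructure:
    """A fully filled ``width x height`` block of original cells."""
    if width < 1 or height < 1:
        raise InvalidArgumentError(f"rectangle dimensions must be >= 1, got {width}x{height}")
    ox, oy = origin
    roles = {
        (ox + i, oy + j): Role.ORIGINAL
        for j in range(height)
        for i in range(width)
    }
    return CellStructure(roles, name=f"rect_{width}x{height}")


def make_ellipse(
    semi_axes: tuple[float, float], center: tuple[float, float] = (0.0, 0.0)
) -> CellStructure:
    """All lattice nodes strictly inside the ellipse (x/a)^2 + (y/b)^2 < 1."""
    a, b = semi_axes
    if a <= 0 or b <= 0:
        raise InvalidArgumentError(f"semi-axes must be positive, got {semi_axes}")
    cx, cy = center
    roles: dict[Node, Role] = {}
    for y in range(math.floor(cy - b), math.ceil(cy + b) + 1):
        for x in range(math.floor(cx - a), math.ceil(cx + a) + 1):
            if ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 < 1.0:
                roles[(x, y)] = Role.ORIGINAL
    if not roles:
        raise EmptyStructureError(f"ellipse {semi_axes} at {center} contains no lattice node")
    return CellStructure(roles, name=f"ellipse_{a}x{b}")


def _rect_nodes(x0: int, y0: int, w: int, h: int) -> set[Node]:
    return {(x0 + i, y0 + j) for j in range(h) for i in range(w)}


# Glyph fixtures as unions of axis-aligned rectangles; coordinates are fixed
# so that node sets are bit-exact across runs.
_GLYPHS: dict[str, set[Node]] = {
    # nonconvex union of two bars
    "L": _rect_nodes(0, 0, 3, 10) | _rect_nodes(0, 0, 8, 3),
    # top bar with central stem, mirror-symmetric about x=4
    "T": _rect_nodes(0, 7, 9, 3) | _rect_nodes(3, 0, 3, 7),
    # trunk with two branch rectangles growing from the top corners
    "two_headed": (
        _rect_nodes(0, 0, 12, 6)
        | _rect_nodes(0, 6, 3, 6)
        | _rect_nodes(9, 6, 3, 6)
    ),
    "plus": _rect_nodes(3, 0, 3, 9) | _rect_nodes(0, 3, 9, 3),
}

GLYPH_IDS = tuple(sorted(_GLYPHS))


def make_glyph(glyph_id: str) -> CellStructure:
    """A deterministic letter-like fixture shape."""
    try:
        nodes = _GLYPHS[glyph_id]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown glyph {glyph_id!r}; available: {', '.join(GLYPH_IDS)}"
        ) from None
    return CellStructure({n: Role.ORIGINAL for n in nodes}, name=f"glyph_{glyph_id}")


# -- amputation -------------------------------------------------------------


def _blastema(control: frozenset[Node], removed: frozenset[Node]) -> frozenset[Node]:
    return frozenset(n for n in control if neighbors8(n) & removed)


def resolve_mask(structure: CellStructure, mask: AmputationMask) -> frozenset[Node]:
    """Normalize a mask (node set or predicate) to an explicit node set."""
    if callable(mask):
        return frozenset(n for n in structure.nodes if mask(n))
    return frozenset(mask)


def amputate(structure: CellStructure, mask: AmputationMask) -> CellStructure:
    """Remove the masked cells, labelling survivors as control cells.

    Returns a new structure; ``blastema`` holds the control cells with at
    least one removed 8-neighbour.  Removing every cell is an error; an
    empty mask warns and returns an unmodified copy.
    """
    removed = resolve_mask(structure, mask)
    nodes = structure.nodes
    if not removed <= nodes:
        raise InvalidAmputationError(
            f"mask contains nodes outside the structure: {sorted(removed - nodes)[:5]}"
        )
    if not removed:
        warnings.warn("empty amputation mask: structure returned unchanged", stacklevel=2)
        return structure.copy()
    if removed == nodes:
        raise InvalidAmputationError("amputation must leave at least one cell")
    roles = {
        n: (Role.REMOVED if n in removed else Role.CONTROL) for n in nodes
    }
    control = frozenset(nodes - removed)
    return CellStructure(roles, name=structure.name, blastema=_blastema(control, removed))
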