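"""PNG rendering of cell structures.

One fixed-size square per lattice node: green for control/original cells,
red for new cells, white for removed-and-not-regenerated sites, yellow for
violating control cells and blue for the worst violator.  The raster is a
convenience view only; the CSV serialization is the canonical output.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Union

from PIL import Image

from .errors import InvalidArgumentError
from .structures import CellStructure, Node, Role

__all__ = ["render_structure", "COLORS"]

COLORS = {
    "background": (230, 230, 230),
    Role.ORIGINAL: (0, 160, 0),
    Role.CONTROL: (0, 160, 0),
    Role.NEW: (220, 30, 30),
    Role.REMOVED: (255, 255, 255),
    "violation": (240, 220, 40),
    "worst": (40, 60, 230),
}


def render_structure(
    structure: CellStructure,
    path: Union[str, Path],
    violations: Optional[Iterable[Node]] = None,
    worst: Optional[Node] = None,
    cell_px: int = 10,
) -> Path:
    """Write a deterministic PNG raster of the structure; returns the path."""
    if cell_px < 1:
        raise InvalidArgumentError("cell_px must be >= 1")
    violations = frozenset(violations or ())
    xmin, ymin, xmax, ymax = structure.bounding_box()
    width = (xmax - xmin + 1) * cell_px
    height = (ymax - ymin + 1) * cell_px
    image = Image.new("RGB", (width, height), COLORS["background"])
    pixels = image.load()
    for (x, y), role in structure.roles.items():
        if (x, y) == worst:
            color = COLORS["worst"]
        elif (x, y) in violations:
            color = COLORS["violation"]
        else:
            color = COLORS[role]
        # y axis points up in lattice coordinates, down in the raster
        px0 = (x - xmin) * cell_px
        py0 = (ymax - y) * cell_px
        for dx in range(cell_px):
            for dy in range(cell_px):
                pixels[px0 + dx, py0 + dy] = color
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    image.save(path, format="PNG")
    return path
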