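"""Distance-decay signal kernels and received-signal fields.

Every cell emits the same signal whose intensity decays with Euclidean
distance d as either d**-n (polynomial family) or exp(-n*d) (exponential
family).  The field value at a node is the sum of kernel contributions from
all source cells, a source never contributing to itself.

Per-node sums are accumulated with ``math.fsum`` so that a field value is a
correctly rounded double independent of source enumeration order.  This
makes fields bit-reproducible and lets independent re-implementations agree
exactly, which the engine's brute-force cross-checks rely on.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import ContractError, InvalidArgumentError, StateError
from .structures import CellStructure, Node, Role

__all__ = [
    "Kernel",
    "SignalField",
    "kernel_eval",
    "compute_field",
    "old_field",
    "new_field",
    "deficit_signal",
    "total_signal",
]

_FAMILIES = ("polynomial", "exponential")
_FAMILY_ALIASES = {"poly": "polynomial", "exp": "exponential"}


@dataclass(frozen=True)
class Kernel:
    """A strictly decreasing, positive decay function of distance.

    ``polynomial`` evaluates d**-n, ``exponential`` evaluates exp(-n*d);
    n must be positive in both families.
    """

    family: str = "polynomial"
    n: float = 2.0

    def __post_init__(self) -> None:
        family = _FAMILY_ALIASES.get(self.family, self.family)
        object.__setattr__(self, "family", family)
        if family not in _FAMILIES:
            raise InvalidArgumentError(f"unknown kernel family {self.family!r}")
        if not self.n > 0:
            raise InvalidArgumentError(f"kernel exponent must be > 0, got {self.n}")

    def __call__(self, d: float) -> float:
        return kernel_eval(self, d)

    def eval_d2(self, d2: np.ndarray) -> np.ndarray:
        """Evaluate on an array of squared distances (all > 0).

        Lattice squared distances are exact small integers, so values are
        computed once per distinct d2 through the scalar math library and
        cached; results are bit-identical to the scalar evaluation path,
        unlike numpy's vectorized pow/exp which can differ in the last ulp.
        """
        uniq, inverse = np.unique(d2, return_inverse=True)
        vals = np.array([_kernel_at_d2(self.family, self.n, float(v)) for v in uniq])
        return vals[inverse].reshape(np.shape(d2))


@lru_cache(maxsize=1 << 20)
def _kernel_at_d2(family: str, n: float, d2: float) -> float:
    d = math.sqrt(d2)
    if family == "polynomial":
        return d ** (-n)
    return math.exp(-n * d)


def kernel_eval(kernel: Kernel, d: float) -> float:
    """Evaluate the kernel at a single positive distance."""
    if not d > 0:
        raise InvalidArgumentError(f"kernel distance must be > 0, got {d}")
    if kernel.family == "polynomial":
        return d ** (-kernel.n)
    return math.exp(-kernel.n * d)


class SignalField(Mapping[Node, float]):
    """An immutable map from lattice nodes to nonnegative signal values."""

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[Node, float]):
        for node, v in values.items():
            if v < 0:
                raise InvalidArgumentError(f"negative signal {v} at node {node}")
        self._values = dict(values)

    def __getitem__(self, node: Node) -> float:
        return self._values[node]

    def __iter__(self) -> Iterator[Node]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def total(self) -> float:
        return math.fsum(self._values.values())

    def to_csv(self) -> str:
        """`x,y,value` CSV with 17 significant digits (round-trip exact)."""
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["x", "y", "value"])
        for x, y in sorted(self._values, key=lambda n: (n[1], n[0])):
            writer.writerow([x, y, format(self._values[(x, y)], ".17g")])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "SignalField":
        reader = csv.reader(io.StringIO(text))
        header = next(reader)
        if header != ["x", "y", "value"]:
            raise InvalidArgumentError(f"bad field CSV header: {header!r}")
        return cls({(int(r[0]), int(r[1])): float(r[2]) for r in reader if r})


def _as_array(nodes: Iterable[Node]) -> tuple[list[Node], np.ndarray]:
    ordered = sorted(set(nodes), key=lambda n: (n[1], n[0]))
    return ordered, np.asarray(ordered, dtype=float)


def field_values(
    sources: Iterable[Node], eval_points: Iterable[Node], kernel: Kernel
) -> tuple[list[Node], np.ndarray]:
    """Field values as (ordered eval nodes, value array).

    Each value is the fsum of kernel contributions from all sources other
    than the evaluation node itself.
    """
    src_list, src = _as_array(sources)
    ev_list, ev = _as_array(eval_points)
    if not src_list or not ev_list:
        raise InvalidArgumentError("sources and eval_points must be nonempty")
    # squared distances are exact in float64 for lattice coordinates
    d2 = (
        (ev[:, 0:1] - src[None, :, 0]) ** 2
        + (ev[:, 1:2] - src[None, :, 1]) ** 2
    )
    self_mask = d2 == 0.0
    d2[self_mask] = 1.0  # placeholder, zeroed below
    contrib = kernel.eval_d2(d2)
    contrib[self_mask] = 0.0
    values = np.array([math.fsum(row) for row in contrib])
    return ev_list, values


def compute_field(
    sources: Iterable[Node], eval_points: Iterable[Node], kernel: Kernel
) -> SignalField:
    """Total signal received at each evaluation node from the source set."""
    nodes, values = field_values(sources, eval_points, kernel)
    return SignalField(dict(zip(nodes, values)))


def old_field(structure: CellStructure, kernel: Kernel) -> SignalField:
    """The remembered signal u*: control cells, sources = whole original set."""
    if not structure.is_amputated:
        raise StateError("old_field requires an amputated structure")
    return compute_field(structure.original_nodes, structure.control, kernel)


def new_field(structure: CellStructure, kernel: Kernel) -> SignalField:
    """The current signal u(t): control cells, sources = control + new cells."""
    if not structure.is_amputated:
        raise StateError("new_field requires an amputated structure")
    sources = structure.control | structure.new
    return compute_field(sources, structure.control, kernel)


def deficit_signal(
    candidate: Node, old: SignalField, new: SignalField, kernel: Kernel
) -> float:
    """z_k: deficit-weighted signal a candidate receives from control cells.

    z_k = sum over control cells i of f(d_ik) * (u*_i - u_i(t)).
    """
    if set(old) != set(new):
        raise ContractError("old and new fields must cover the same control nodes")
    cx, cy = candidate
    terms = []
    for (x, y), u_star in old.items():
        d = math.sqrt((x - cx) ** 2 + (y - cy) ** 2)
        terms.append(kernel_eval(kernel, d) * (u_star - new[(x, y)]))
    return math.fsum(terms)


def total_signal(field: SignalField) -> float:
    """S = sum of field values over its nodes."""
    return field.total()
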