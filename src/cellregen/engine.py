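"""Greedy signal-matching regeneration engine.

After amputation each control cell remembers its pre-amputation signal u*
and measures the current signal u(t).  One cell is added per discrete time
step, chosen among lattice sites that

1. touch the blastema or an earlier new cell (growth continuity),
2. would not push any measured cell's signal above its remembered value
   beyond a relative tolerance epsilon (admissibility), and
3. maximize either the total signal added to measured cells (rule 3a) or
   the deficit-weighted signal received from measured cells (rule 3b).

By default (``new_cell_memory=True``) a newly placed cell joins the
measured set, with the original structure's field value at its site as its
remembered signal.  This inheritance is what keeps growth filling the
wound row by row instead of wrapping a shell of high-scoring cells around
the intact boundary: a misplaced cell's inherited memory is immediately
saturated and blocks further growth around it.  Setting
``new_cell_memory=False`` restricts every check and score to the surviving
control cells only; in that literal mode even modest straight cuts fail to
regenerate because boundary-hugging sites outscore the wound interior.

The run stops with status ``exact`` when every relative deficit
(u* - u)/u* falls to the stop threshold, ``stalled`` when no admissible
candidate remains, ``violation`` when a measured cell overshoots u* beyond
epsilon (possible only with the admissibility filter disabled), or
``step_limit``.

All scores and field values are order-independent correctly rounded sums
(see :mod:`cellregen.signals`), so a naive per-candidate re-computation
reproduces the engine's choices bit-for-bit, ties included.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import math
from dataclasses import dataclass, field as dataclass_field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    CellRegenError,
    ContractError,
    InfeasibleTargetError,
    InvalidArgumentError,
    StateError,
)
from .signals import Kernel, SignalField, new_field, old_field
from .structures import CellStructure, Node, Role, neighbors8

__all__ = [
    "RegenerationConfig",
    "RegenerationResult",
    "OrganizerSpec",
    "TraceStep",
    "NoAdmissibleCandidate",
    "candidate_set",
    "admissible",
    "select_3a",
    "select_3b",
    "run",
    "detect_violations",
    "grow_from_organizer",
]

RULES = ("3a", "3b")
_TIE_BREAKS = {
    "yx": lambda n: (n[1], n[0]),
    "xy": lambda n: (n[0], n[1]),
}

STATUS_EXACT = "exact"
STATUS_STALLED = "stalled"
STATUS_VIOLATION = "violation"
STATUS_STEP_LIMIT = "step_limit"


class NoAdmissibleCandidate(CellRegenError):
    """Raised by the selection rules when every candidate is inadmissible."""


@dataclass(frozen=True)
class RegenerationConfig:
    """Run parameters for the greedy regeneration loop.

    epsilon is the relative overshoot tolerance of the admissibility check;
    stop_deficit is the relative undershoot at which regeneration is
    declared complete; search_margin bounds the candidate window around the
    original structure's bounding box; new_cell_memory controls whether
    placed cells join the measured set with an inherited remembered signal.
    """

    rule: str = "3b"
    enforce_condition2: bool = True
    epsilon: float = 1e-14
    stop_deficit: float = 1e-9
    max_steps: int = 10_000
    search_margin: int = 5
    tie_break: str = "yx"
    new_cell_memory: bool = True

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise InvalidArgumentError(f"rule must be one of {RULES}, got {self.rule!r}")
        if not self.epsilon > 0:
            raise InvalidArgumentError(f"epsilon must be > 0, got {self.epsilon}")
        if self.stop_deficit < 0:
            raise InvalidArgumentError("stop_deficit must be >= 0")
        if self.max_steps < 1:
            raise InvalidArgumentError("max_steps must be >= 1")
        if self.search_margin < 0:
            raise InvalidArgumentError("search_margin must be >= 0")
        if self.tie_break not in _TIE_BREAKS:
            raise InvalidArgumentError(
                f"tie_break must be one of {sorted(_TIE_BREAKS)}, got {self.tie_break!r}"
            )

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "enforce_condition2": self.enforce_condition2,
            "epsilon": self.epsilon,
            "stop_deficit": self.stop_deficit,
            "max_steps": self.max_steps,
            "search_margin": self.search_margin,
            "tie_break": self.tie_break,
            "new_cell_memory": self.new_cell_memory,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "RegenerationConfig":
        known = set(cls().to_dict())
        unknown = set(doc) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


@dataclass(frozen=True)
class TraceStep:
    step: int
    node: Node
    S_t: float
    max_rel_deficit: float


@dataclass
class RegenerationResult:
    """Outcome of a regeneration or morphogenesis run."""

    structure: CellStructure
    status: str
    steps_taken: int
    trace: list[TraceStep]
    violations: dict[Node, float] = dataclass_field(default_factory=dict)
    worst_violation: Optional[Node] = None

    @property
    def new_cells(self) -> frozenset[Node]:
        return self.structure.new

    def trace_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["step", "x", "y", "S_t", "max_rel_deficit", "status"])
        last = len(self.trace)
        for entry in self.trace:
            writer.writerow(
                [
                    entry.step,
                    entry.node[0],
                    entry.node[1],
                    format(entry.S_t, ".17g"),
                    format(entry.max_rel_deficit, ".17g"),
                    self.status if entry.step == last else "",
                ]
            )
        return buf.getvalue()


@dataclass(frozen=True)
class OrganizerSpec:
    """An organizing center with a prescribed target signal per cell.

    ``reference`` optionally names the full structure the target field was
    measured from; when given, newly grown cells can inherit remembered
    values from it, which makes organizer growth reduce to regeneration of
    the reference shape.  Without it the prescribed values on the organizer
    cells are the only constraints.
    """

    structure: CellStructure
    target: SignalField
    reference: Optional[CellStructure] = None


# -- candidate generation ---------------------------------------------------


def _search_window(structure: CellStructure, margin: int) -> tuple[int, int, int, int]:
    xs = [n[0] for n in structure.original_nodes]
    ys = [n[1] for n in structure.original_nodes]
    return min(xs) - margin, min(ys) - margin, max(xs) + margin, max(ys) + margin


def candidate_set(
    structure: CellStructure,
    search_margin: int = 5,
    window: Optional[tuple[int, int, int, int]] = None,
) -> frozenset[Node]:
    """Empty lattice sites adjacent to the blastema or to a new cell.

    Only sites within the original bounding box expanded by search_margin
    (or an explicit ``window``) are considered; condition-2 admissibility
    is checked separately.
    """
    if not structure.blastema:
        raise StateError("structure has no blastema; amputate first")
    xmin, ymin, xmax, ymax = window or _search_window(structure, search_margin)
    occupied = structure.occupied
    seeds = structure.blastema | structure.new
    candidates = set()
    for seed in seeds:
        for node in neighbors8(seed):
            if node in occupied:
                continue
            if xmin <= node[0] <= xmax and ymin <= node[1] <= ymax:
                candidates.add(node)
    return frozenset(candidates)


# -- admissibility and selection (scalar reference forms) -------------------


def admissible(
    candidate: Node,
    old: SignalField,
    new: SignalField,
    kernel: Kernel,
    epsilon: float,
    enforce_condition2: bool = True,
) -> bool:
    """Would placing the candidate keep every control cell within tolerance?

    True iff (u_i + f(d_ik) - u*_i) / u*_i < epsilon for every control cell i.
    """
    if not enforce_condition2:
        return True
    if set(old) != set(new):
        raise ContractError("old and new fields must cover the same control nodes")
    cx, cy = candidate
    for (x, y), u_star in old.items():
        d = math.sqrt((x - cx) ** 2 + (y - cy) ** 2)
        predicted = new[(x, y)] + kernel(d)
        if not (predicted - u_star) / u_star < epsilon:
            return False
    return True


def _added_signal(candidate: Node, controls: Iterable[Node], kernel: Kernel) -> float:
    cx, cy = candidate
    return math.fsum(
        kernel(math.sqrt((x - cx) ** 2 + (y - cy) ** 2)) for x, y in controls
    )


def _deficit_score(
    candidate: Node, old: SignalField, new: SignalField, kernel: Kernel
) -> float:
    cx, cy = candidate
    return math.fsum(
        kernel(math.sqrt((n[0] - cx) ** 2 + (n[1] - cy) ** 2)) * (old[n] - new[n])
        for n in old
    )


def _select(
    candidates: Iterable[Node],
    old: SignalField,
    new: SignalField,
    kernel: Kernel,
    config: RegenerationConfig,
    rule: str,
) -> Node:
    key = _TIE_BREAKS[config.tie_break]
    best: Optional[Node] = None
    best_score = -math.inf
    for candidate in sorted(candidates, key=key):
        if not admissible(
            candidate, old, new, kernel, config.epsilon, config.enforce_condition2
        ):
            continue
        if rule == "3a":
            score = _added_signal(candidate, old, kernel)
        else:
            score = _deficit_score(candidate, old, new, kernel)
        if score > best_score:
            best, best_score = candidate, score
    if best is None:
        raise NoAdmissibleCandidate("no candidate satisfies conditions 1 and 2")
    return best


def select_3a(
    candidates: Iterable[Node],
    old: SignalField,
    new: SignalField,
    kernel: Kernel,
    config: RegenerationConfig = RegenerationConfig(rule="3a"),
) -> Node:
    """Admissible candidate adding the most total signal to control cells."""
    return _select(candidates, old, new, kernel, config, "3a")


def select_3b(
    candidates: Iterable[Node],
    old: SignalField,
    new: SignalField,
    kernel: Kernel,
    config: RegenerationConfig = RegenerationConfig(rule="3b"),
) -> Node:
    """Admissible candidate receiving the most deficit-weighted signal z_k."""
    return _select(candidates, old, new, kernel, config, "3b")


def detect_violations(
    old: SignalField, new: SignalField, epsilon: float
) -> tuple[dict[Node, float], Optional[Node]]:
    """Control cells with (u_i - u*_i)/u*_i >= epsilon; worst by u_i - u*_i."""
    if set(old) != set(new):
        raise ContractError("old and new fields must cover the same control nodes")
    violations: dict[Node, float] = {}
    worst: Optional[Node] = None
    worst_abs = -math.inf
    for node in old:
        u_star, u = old[node], new[node]
        rel = (u - u_star) / u_star
        if rel >= epsilon:
            violations[node] = rel
            if u - u_star > worst_abs:
                worst_abs = u - u_star
                worst = node
    return violations, worst


# -- main loop (vectorized, bit-identical to the scalar forms) --------------


def _control_arrays(
    controls: Sequence[Node],
) -> np.ndarray:
    return np.asarray(controls, dtype=float)


def _field_on(
    sources: Iterable[Node], eval_nodes: Sequence[Node], kernel: Kernel
) -> tuple[Sequence[Node], np.ndarray]:
    """Field values on eval_nodes, preserving their order (cf. compute_field)."""
    src = np.asarray(sorted(sources), dtype=float)
    ev = np.asarray(eval_nodes, dtype=float)
    d2 = (
        (ev[:, 0:1] - src[None, :, 0]) ** 2
        + (ev[:, 1:2] - src[None, :, 1]) ** 2
    )
    self_mask = d2 == 0.0
    d2[self_mask] = 1.0
    contrib = kernel.eval_d2(d2)
    contrib[self_mask] = 0.0
    return eval_nodes, np.array([math.fsum(row) for row in contrib])


def _candidate_matrix(
    candidates: Sequence[Node], control_xy: np.ndarray, kernel: Kernel
) -> np.ndarray:
    """Row c = kernel contributions of candidate c to every control cell."""
    cand = np.asarray(candidates, dtype=float)
    d2 = (
        (cand[:, 0:1] - control_xy[None, :, 0]) ** 2
        + (cand[:, 1:2] - control_xy[None, :, 1]) ** 2
    )
    return kernel.eval_d2(d2)


def _memory_from(nodes: frozenset[Node], kernel: Kernel):
    """Remembered-signal oracle: the field of ``nodes`` at any lattice site."""

    def memory(p: Node) -> float:
        px, py = p
        return math.fsum(
            kernel(math.sqrt((x - px) ** 2 + (y - py) ** 2))
            for x, y in nodes
            if (x, y) != p
        )

    return memory


def run(
    structure: CellStructure,
    kernel: Kernel,
    config: RegenerationConfig = RegenerationConfig(),
    *,
    target: Optional[SignalField] = None,
    memory=None,
) -> RegenerationResult:
    """Run the greedy regeneration loop on an amputated structure.

    ``target`` overrides the remembered field u* on the control cells (used
    by morphogenesis); by default it is measured from the full original
    structure.  ``memory`` is the remembered-signal oracle for newly placed
    cells (a callable node -> u*); it defaults to the original structure's
    field and is ignored when ``config.new_cell_memory`` is false.
    """
    state = structure.copy()
    if not state.blastema:
        raise StateError("cannot regenerate: structure has an empty blastema")

    old = target if target is not None else old_field(state, kernel)
    controls = sorted(state.control, key=lambda n: (n[1], n[0]))
    if set(old) != set(controls):
        raise ContractError("target field must cover exactly the control cells")
    if config.new_cell_memory and memory is None:
        memory = _memory_from(state.original_nodes, kernel)
    inherit = config.new_cell_memory and memory is not None
    # the candidate window is anchored to the pre-run structure: placed cells
    # overwrite removed roles, which would otherwise shrink the bounding box
    window = _search_window(state, config.search_margin)

    # measured cells: controls first, then new cells in placement order
    measured: list[Node] = list(controls)
    u_star = [old[n] for n in controls]

    tie_key = _TIE_BREAKS[config.tie_break]
    trace: list[TraceStep] = []
    steps = 0
    violations: dict[Node, float] = {}
    worst: Optional[Node] = None
    n_controls = len(controls)

    def current_values() -> np.ndarray:
        sources = state.control | state.new
        _, values = _field_on(sources, measured, kernel)
        return values

    u = current_values()
    while True:
        ustar_arr = np.array(u_star)
        overshoot = (u - ustar_arr) / ustar_arr
        if np.any(overshoot >= config.epsilon):
            status = STATUS_VIOLATION
            old_f = SignalField(dict(zip(measured, ustar_arr)))
            new_f = SignalField(dict(zip(measured, u)))
            violations, worst = detect_violations(old_f, new_f, config.epsilon)
            break
        max_rel_deficit = float(np.max((ustar_arr - u) / ustar_arr))
        if max_rel_deficit <= config.stop_deficit:
            status = STATUS_EXACT
            break
        if steps >= config.max_steps:
            status = STATUS_STEP_LIMIT
            break

        candidates = sorted(
            candidate_set(state, config.search_margin, window=window), key=tie_key
        )
        if not candidates:
            status = STATUS_STALLED
            break
        measured_xy = _control_arrays(measured)
        add = _candidate_matrix(candidates, measured_xy, kernel)
        if config.enforce_condition2:
            ok = np.all(
                (u[None, :] + add - ustar_arr[None, :]) / ustar_arr[None, :]
                < config.epsilon,
                axis=1,
            )
        else:
            ok = np.ones(len(candidates), dtype=bool)
        if not np.any(ok):
            status = STATUS_STALLED
            break
        if config.rule == "3a":
            scores = np.array([math.fsum(row) for row in add])
        else:
            deficit = ustar_arr - u
            scores = np.array([math.fsum(row * deficit) for row in add])
        scores[~ok] = -np.inf
        chosen = candidates[int(np.argmax(scores))]

        state.add_new(chosen)
        if inherit:
            measured.append(chosen)
            u_star.append(memory(chosen))
        steps += 1
        u = current_values()
        ustar_arr = np.array(u_star)
        trace.append(
            TraceStep(
                step=steps,
                node=chosen,
                S_t=math.fsum(u[:n_controls]),
                max_rel_deficit=float(np.max((ustar_arr - u) / ustar_arr)),
            )
        )

    return RegenerationResult(
        structure=state,
        status=status,
        steps_taken=steps,
        trace=trace,
        violations=violations,
        worst_violation=worst,
    )


def grow_from_organizer(
    organizer: OrganizerSpec,
    kernel: Kernel,
    config: RegenerationConfig = RegenerationConfig(),
) -> RegenerationResult:
    """Grow new structure around an organizing center.

    The organizer's cells act as control cells whose remembered signal is
    the prescribed target; its boundary cells seed growth.  The prescribed
    target must not fall below the organizer's self-generated field.  New
    cells inherit remembered values from the reference structure when one
    is named; otherwise only the organizer cells constrain growth.
    """
    base = organizer.structure
    nodes = base.nodes
    if set(organizer.target) != nodes:
        raise ContractError("target field must cover exactly the organizer cells")
    from .signals import compute_field

    self_f = compute_field(nodes, nodes, kernel)
    for node in nodes:
        if organizer.target[node] < self_f[node] * (1.0 - 1e-12):
            raise InfeasibleTargetError(
                f"prescribed signal at {node} is below the self-generated field"
            )
    boundary = frozenset(n for n in nodes if neighbors8(n) - nodes)
    state = CellStructure(
        {n: Role.CONTROL for n in nodes}, name=base.name or "organizer", blastema=boundary
    )
    memory = None
    if organizer.reference is not None:
        memory = _memory_from(organizer.reference.nodes, kernel)
    elif config.new_cell_memory:
        config = dataclasses.replace(config, new_cell_memory=False)
    return run(state, kernel, config, target=organizer.target, memory=memory)
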