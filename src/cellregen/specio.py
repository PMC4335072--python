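"""Run-spec documents: declarative YAML/JSON description of a simulation.

A run spec names a shape generator, an amputation mask, a kernel and the
engine configuration.  Loading is strict: unknown keys are rejected with
the offending key path so that typos fail loudly instead of silently
falling back to defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Union

import yaml

from .engine import RegenerationConfig
from .errors import CellRegenError, SpecError
from .signals import Kernel
from .structures import (
    CellStructure,
    Node,
    make_ellipse,
    make_glyph,
    make_rectangle,
)

__all__ = ["RunSpec", "load_spec", "save_spec", "build_structure", "build_mask", "build_kernel"]

_SHAPE_KEYS = {
    "rectangle": {"kind", "width", "height", "origin"},
    "ellipse": {"kind", "semi_axes", "center"},
    "glyph": {"kind", "id"},
}
_MASK_KEYS = {
    "half_plane": {"kind", "axis", "op", "value"},
    "rect": {"kind", "x0", "y0", "width", "height"},
    "nodes": {"kind", "nodes"},
}
_TOP_KEYS = {"shape", "amputation", "kernel", "config", "output_dir", "render"}


def _check_keys(doc: dict, allowed: set, path: str) -> None:
    unknown = set(doc) - allowed
    if unknown:
        raise SpecError(f"unknown keys {sorted(unknown)}", path)


@dataclass(frozen=True)
class RunSpec:
    """A fully reproducible simulation description."""

    shape: dict
    amputation: dict
    kernel: Kernel = Kernel()
    config: RegenerationConfig = field(default_factory=RegenerationConfig)
    output_dir: str = "out"
    render: bool = True

    def to_dict(self) -> dict:
        return {
            "shape": dict(self.shape),
            "amputation": dict(self.amputation),
            "kernel": {"family": self.kernel.family, "n": self.kernel.n},
            "config": self.config.to_dict(),
            "output_dir": self.output_dir,
            "render": self.render,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "RunSpec":
        if not isinstance(doc, dict):
            raise SpecError("spec document must be a mapping")
        _check_keys(doc, _TOP_KEYS, "")
        for required in ("shape", "amputation"):
            if required not in doc:
                raise SpecError("required key missing", required)

        shape = doc["shape"]
        kind = shape.get("kind")
        if kind not in _SHAPE_KEYS:
            raise SpecError(
                f"kind must be one of {sorted(_SHAPE_KEYS)}, got {kind!r}", "shape.kind"
            )
        _check_keys(shape, _SHAPE_KEYS[kind], "shape")

        mask = doc["amputation"]
        mkind = mask.get("kind")
        if mkind not in _MASK_KEYS:
            raise SpecError(
                f"kind must be one of {sorted(_MASK_KEYS)}, got {mkind!r}",
                "amputation.kind",
            )
        _check_keys(mask, _MASK_KEYS[mkind], "amputation")

        kdoc = doc.get("kernel", {})
        _check_keys(kdoc, {"family", "n"}, "kernel")
        try:
            kernel = Kernel(kdoc.get("family", "polynomial"), kdoc.get("n", 2.0))
        except CellRegenError as exc:
            raise SpecError(str(exc), "kernel") from exc

        try:
            config = RegenerationConfig.from_dict(doc.get("config", {}))
        except (CellRegenError, TypeError) as exc:
            raise SpecError(str(exc), "config") from exc

        return cls(
            shape=dict(shape),
            amputation=dict(mask),
            kernel=kernel,
            config=config,
            output_dir=doc.get("output_dir", "out"),
            render=bool(doc.get("render", True)),
        )


def load_spec(path: Union[str, Path]) -> RunSpec:
    """Load a YAML (.yaml/.yml) or JSON (.json) run spec."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix == ".json":
            doc = json.loads(text)
        else:
            doc = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise SpecError(f"cannot parse {path.name}: {exc}") from exc
    return RunSpec.from_dict(doc)


def save_spec(spec: RunSpec, path: Union[str, Path]) -> None:
    path = Path(path)
    doc = spec.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


def build_structure(spec: RunSpec) -> CellStructure:
    shape = spec.shape
    kind = shape["kind"]
    try:
        if kind == "rectangle":
            origin = tuple(shape.get("origin", (0, 0)))
            return make_rectangle(shape["width"], shape["height"], origin)
        if kind == "ellipse":
            center = tuple(shape.get("center", (0.0, 0.0)))
            return make_ellipse(tuple(shape["semi_axes"]), center)
        return make_glyph(shape["id"])
    except KeyError as exc:
        raise SpecError(f"missing shape parameter {exc}", "shape") from exc
    except CellRegenError as exc:
        raise SpecError(str(exc), "shape") from exc


def build_mask(spec: RunSpec, structure: CellStructure) -> frozenset[Node]:
    mask = spec.amputation
    kind = mask["kind"]
    try:
        if kind == "half_plane":
            axis = {"x": 0, "y": 1}[mask["axis"]]
            op = mask.get("op", "ge")
            value = mask["value"]
            if op == "ge":
                return frozenset(n for n in structure.nodes if n[axis] >= value)
            if op == "le":
                return frozenset(n for n in structure.nodes if n[axis] <= value)
            raise SpecError(f"op must be 'ge' or 'le', got {op!r}", "amputation.op")
        if kind == "rect":
            x0, y0 = mask["x0"], mask["y0"]
            w, h = mask["width"], mask["height"]
            return frozenset(
                n
                for n in structure.nodes
                if x0 <= n[0] < x0 + w and y0 <= n[1] < y0 + h
            )
        return frozenset((int(x), int(y)) for x, y in mask["nodes"])
    except KeyError as exc:
        raise SpecError(f"missing amputation parameter {exc}", "amputation") from exc


def build_kernel(spec: RunSpec) -> Kernel:
    return spec.kernel
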