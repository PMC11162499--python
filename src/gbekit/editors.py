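"""Base-editor definitions: conversion chemistry, PAM, and editing windows.

A base editor is modelled as pure data: which base it excises/converts
(``BaseConversion``), where along the 20-nt protospacer it is active
(``EditingWindow``, 1-based positions with the PAM at 21-23), and which PAM
it requires. The shipped registry covers the deaminase-free glycosylase
editors (gTBE/gCBE/gGBE families, TSBE3, DAF-TBE/-CBE families, CGBE1,
CGBE-CDG) plus canonical ABE/CBE for cross-editor comparisons.

Window semantics follow the field's convention: the *editable* range is any
position with detectable activity, the *optimal* window is the
high-efficiency sub-range, and ``peak`` (when known) is the single most
efficient position. Editors for which only one published range exists store
it as both optimal and editable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from types import MappingProxyType
from typing import Iterator, Mapping

from ._seq import DNA, validate_iupac_pattern

__all__ = [
    "BaseConversion",
    "EditingWindow",
    "EditorSpec",
    "EditorRegistry",
    "builtin_editors",
    "can_edit",
]


@dataclass(frozen=True)
class BaseConversion:
    """Chemistry of a single-base conversion.

    Parameters
    ----------
    source_base
        The base the editor acts on (e.g. ``"T"`` for a thymine editor).
    product_bases
        All observed product bases, ordered by abundance.
    predominant
        The major products (e.g. T→C/G for gTBE, the "T-to-S" outcome).
    minor
        Trace products observed but excluded from design-time intended
        edits (e.g. gTBE's low-level T→A).
    """

    source_base: str
    product_bases: tuple[str, ...]
    predominant: tuple[str, ...]
    minor: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.source_base not in DNA:
            raise ValueError(f"source_base must be one of {DNA}: {self.source_base!r}")
        if not self.product_bases:
            raise ValueError("product_bases must be non-empty")
        if self.source_base in self.product_bases:
            raise ValueError("source_base cannot be its own product")
        for group, name in ((self.predominant, "predominant"), (self.minor, "minor")):
            if not set(group) <= set(self.product_bases):
                raise ValueError(f"{name} must be a subset of product_bases")

    @property
    def design_products(self) -> tuple[str, ...]:
        """Products considered intended edits at design time (minor excluded)."""
        return tuple(b for b in self.product_bases if b not in self.minor)


@dataclass(frozen=True)
class EditingWindow:
    """Protospacer positions (1-based, PAM at 21-23) where an editor acts."""

    editable_start: int
    editable_end: int
    optimal_start: int
    optimal_end: int
    peak: int | None = None

    def __post_init__(self) -> None:
        ok = (
            1 <= self.editable_start <= self.optimal_start
            <= self.optimal_end <= self.editable_end <= 20
        )
        if not ok:
            raise ValueError(
                "require 1 <= editable_start <= optimal_start <= optimal_end "
                f"<= editable_end <= 20, got {self}"
            )
        if self.peak is not None and not (
            self.optimal_start <= self.peak <= self.optimal_end
        ):
            raise ValueError(f"peak {self.peak} outside optimal window")

    def contains(self, position: int, mode: str = "optimal") -> bool:
        if mode == "optimal":
            return self.optimal_start <= position <= self.optimal_end
        if mode == "editable":
            return self.editable_start <= position <= self.editable_end
        raise ValueError(f"mode must be 'optimal' or 'editable', got {mode!r}")

    @property
    def optimal(self) -> tuple[int, int]:
        return (self.optimal_start, self.optimal_end)

    @property
    def editable(self) -> tuple[int, int]:
        return (self.editable_start, self.editable_end)


@dataclass(frozen=True)
class EditorSpec:
    """One base editor: name, chemistry, window, PAM, nickase label."""

    name: str
    conversion: BaseConversion
    window: EditingWindow
    pam: str = "NGG"
    nickase: str = "nCas9(D10A)"

    def __post_init__(self) -> None:
        if len(self.pam) != 3:
            raise ValueError(f"PAM must be 3 nt, got {self.pam!r}")
        object.__setattr__(self, "pam", validate_iupac_pattern(self.pam))

    def to_dict(self) -> dict:
        c, w = self.conversion, self.window
        return {
            "name": self.name,
            "conversion": {
                "source_base": c.source_base,
                "product_bases": list(c.product_bases),
                "predominant": list(c.predominant),
                "minor": list(c.minor),
            },
            "window": {
                "editable": [w.editable_start, w.editable_end],
                "optimal": [w.optimal_start, w.optimal_end],
                "peak": w.peak,
            },
            "pam": self.pam,
            "nickase": self.nickase,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EditorSpec":
        c, w = d["conversion"], d["window"]
        return cls(
            name=d["name"],
            conversion=BaseConversion(
                source_base=c["source_base"],
                product_bases=tuple(c["product_bases"]),
                predominant=tuple(c["predominant"]),
                minor=tuple(c.get("minor", ())),
            ),
            window=EditingWindow(
                editable_start=w["editable"][0],
                editable_end=w["editable"][1],
                optimal_start=w["optimal"][0],
                optimal_end=w["optimal"][1],
                peak=w.get("peak"),
            ),
            pam=d.get("pam", "NGG"),
            nickase=d.get("nickase", "nCas9(D10A)"),
        )


class EditorRegistry(Mapping):
    """Immutable name -> :class:`EditorSpec` mapping."""

    def __init__(self, editors: Mapping[str, EditorSpec] | list[EditorSpec]):
        if not isinstance(editors, Mapping):
            editors = {e.name: e for e in editors}
        for name, spec in editors.items():
            if name != spec.name:
                raise ValueError(f"registry key {name!r} != editor name {spec.name!r}")
        self._editors = MappingProxyType(dict(editors))

    def __getitem__(self, name: str) -> EditorSpec:
        return self._editors[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._editors)

    def __len__(self) -> int:
        return len(self._editors)

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(
            {"editors": [e.to_dict() for e in self._editors.values()]},
            indent=indent,
        )

    @classmethod
    def from_json(cls, text: str) -> "EditorRegistry":
        data = json.loads(text)
        return cls([EditorSpec.from_dict(d) for d in data["editors"]])


def _tbe_chem() -> BaseConversion:
    # T-to-S (C or G) predominant; low-level T-to-A recorded but minor.
    return BaseConversion("T", ("C", "G", "A"), predominant=("C", "G"), minor=("A",))


def _gcbe_chem() -> BaseConversion:
    # C-to-G predominant with secondary C-to-T; very few C-to-A.
    return BaseConversion("C", ("G", "T", "A"), predominant=("G",), minor=("A",))


def _cgbe_chem() -> BaseConversion:
    return BaseConversion("C", ("G", "T", "A"), predominant=("G",), minor=("A",))


def builtin_editors() -> EditorRegistry:
    """Registry of every editor characterised in the underlying study.

    Windows are the published ones where available. Canonical ABE/CBE and
    gGBEv6.3 windows are community-convention defaults (ABE/CBE optimal 4-8,
    editable 3-9; gGBE optimal 4-8) because no window for them is asserted
    by the study; override via a JSON editor config if your assay says
    otherwise.
    """
    W = EditingWindow
    editors = [
        # --- thymine editors (T -> C/G) ---
        EditorSpec("gTBEv3", _tbe_chem(), W(2, 11, 3, 7, peak=5)),
        EditorSpec("gTBEv4", _tbe_chem(), W(7, 13, 7, 13)),
        EditorSpec("gTBEv5", _tbe_chem(), W(5, 9, 5, 9)),
        EditorSpec("TSBE3", _tbe_chem(), W(4, 9, 4, 9)),
        EditorSpec("DAF-TBE", _tbe_chem(), W(2, 6, 2, 6)),
        EditorSpec("DAF-TBE2", _tbe_chem(), W(9, 13, 9, 13)),
        # --- cytosine transversion editors (C -> G predominant) ---
        EditorSpec("gCBEv2", _gcbe_chem(), W(2, 9, 2, 6)),
        EditorSpec("gCBEv3", _gcbe_chem(), W(2, 11, 2, 11)),
        EditorSpec("CGBE1", _cgbe_chem(), W(4, 10, 5, 7)),
        EditorSpec("CGBE-CDG", _cgbe_chem(), W(2, 9, 2, 9)),
        EditorSpec("DAF-CBE", _cgbe_chem(), W(2, 9, 2, 9)),
        EditorSpec("DAF-CBE2", _cgbe_chem(), W(9, 12, 9, 12)),
        # --- canonical deaminase editors ---
        EditorSpec("ABE", BaseConversion("A", ("G",), ("G",)), W(3, 9, 4, 8)),
        EditorSpec("CBE", BaseConversion("C", ("T",), ("T",)), W(3, 9, 4, 8)),
        # --- guanine editor ---
        EditorSpec("gGBE", BaseConversion("G", ("C", "T"), ("C", "T")), W(4, 8, 4, 8)),
    ]
    return EditorRegistry(editors)


def default_registry() -> EditorRegistry:
    """Registry loaded from the shipped JSON config (identical to builtins)."""
    text = resources.files("gbekit.data").joinpath("editors.json").read_text()
    return EditorRegistry.from_json(text)


def can_edit(editor: EditorSpec, base: str, position: int, mode: str = "optimal") -> bool:
    """True iff ``editor`` converts ``base`` at protospacer ``position``.

    ``position`` is 1-based on the protospacer (PAM at 21-23); ``mode``
    selects the optimal or the wider editable window.
    """
    if not 1 <= position <= 20:
        raise ValueError(f"protospacer position must be in 1..20, got {position}")
    return (
        base.upper() == editor.conversion.source_base
        and editor.window.contains(position, mode)
    )
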