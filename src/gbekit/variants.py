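"""UNG residue numbering and scanning-mutagenesis planning.

Human uracil DNA glycosylase has two isoforms from alternative
transcription starts: mitochondrial UNG1 (304 aa) and nuclear UNG2
(313 aa). They share the catalytic domain; UNG2 numbering is UNG1
numbering plus a constant offset of 9 (e.g. UNG1 Y147 == UNG2 Y156,
UNG1 N204 == UNG2 N213).

The planner reproduces the segment-scanning mutagenesis idiom used to
engineer glycosylase-based editors: a region is split into 8-residue
segments and every residue is substituted once (alanine scan with the
A>V fallback for native alanines, or X>R / X>D / X>V scans), plus
site-saturation at a single residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from ._seq import AMINO_ACIDS

UNG2_OFFSET = 9
SEGMENT_LENGTH = 8

SCHEMES = ("X>A", "X>R", "X>D", "X>V", "saturation")
_SCAN_TARGET = {"X>A": "A", "X>R": "R", "X>D": "D", "X>V": "V"}


def map_ung1_to_ung2(position: int) -> int:
    """UNG1 residue index -> equivalent UNG2 residue index (offset +9)."""
    if position < 1:
        raise ValueError(f"residue position must be >= 1, got {position}")
    return position + UNG2_OFFSET


def map_ung2_to_ung1(position: int) -> int:
    """Inverse of :func:`map_ung1_to_ung2`."""
    if position < 1:
        raise ValueError(f"residue position must be >= 1, got {position}")
    result = position - UNG2_OFFSET
    if result < 1:
        raise ValueError(
            f"UNG2 residue {position} has no UNG1 equivalent (N-terminal extension)"
        )
    return result


@dataclass(frozen=True)
class ResidueVariant:
    position: int  # 1-based residue index
    from_aa: str
    to_aa: str
    isoform: str = "UNG2"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.from_aa == self.to_aa:
            raise ValueError(f"no-op substitution at {self.position}")
        if self.isoform not in ("UNG1", "UNG2"):
            raise ValueError(f"isoform must be UNG1 or UNG2, got {self.isoform!r}")

    def __str__(self) -> str:
        return f"{self.from_aa}{self.position}{self.to_aa}"


@dataclass(frozen=True)
class MutagenesisPlan:
    region_start: int
    region_end: int
    scheme: str
    variants: tuple[ResidueVariant, ...]
    segments: tuple[tuple[int, int], ...] = field(default=())

    def segment_index(self, position: int) -> int | None:
        for i, (s, e) in enumerate(self.segments):
            if s <= position <= e:
                return i
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "position": v.position,
                "from": v.from_aa,
                "to": v.to_aa,
                "isoform": v.isoform,
                "segment_index": self.segment_index(v.position),
            }
            for v in self.variants
        ]
        return pd.DataFrame(rows, columns=["position", "from", "to", "isoform", "segment_index"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep=".")


def segment_region(start: int, end: int, length: int = SEGMENT_LENGTH) -> tuple[tuple[int, int], ...]:
    """Left-aligned partition of [start, end] into ``length``-residue segments."""
    if end < start:
        raise ValueError("region end before start")
    n = math.ceil((end - start + 1) / length)
    return tuple(
        (start + i * length, min(start + (i + 1) * length - 1, end)) for i in range(n)
    )


def plan_scanning_mutagenesis(
    protein_seq: str,
    region: tuple[int, int],
    scheme: str,
    isoform: str = "UNG2",
) -> MutagenesisPlan:
    """Plan one mutagenesis round over ``region`` (1-based inclusive).

    Scanning schemes propose one substitution per residue: ``X>A`` replaces
    every residue with alanine, falling back to A>V where the native residue
    already is alanine; ``X>R``/``X>D``/``X>V`` replace with the scheme's
    residue and skip natives equal to it (no fallback is defined for those
    scans). ``saturation`` proposes all 19 non-native residues at a
    single position (region must be one residue wide).
    """
    start, end = region
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    if not (1 <= start <= end <= len(protein_seq)):
        raise ValueError(f"region {region} outside sequence of length {len(protein_seq)}")
    bad = set(protein_seq[start - 1 : end]) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid amino-acid letters in region: {sorted(bad)}")

    variants: list[ResidueVariant] = []
    if scheme == "saturation":
        if start != end:
            raise ValueError("saturation scheme requires a single-residue region")
        native = protein_seq[start - 1]
        variants = [
            ResidueVariant(start, native, aa, isoform)
            for aa in AMINO_ACIDS
            if aa != native
        ]
    else:
        target = _SCAN_TARGET[scheme]
        for pos in range(start, end + 1):
            native = protein_seq[pos - 1]
            if native == target:
                if scheme == "X>A":
                    variants.append(ResidueVariant(pos, native, "V", isoform))
                # other scans: native equals scheme target -> skipped
            else:
                variants.append(ResidueVariant(pos, native, target, isoform))

    return MutagenesisPlan(
        region_start=start,
        region_end=end,
        scheme=scheme,
        variants=tuple(variants),
        segments=segment_region(start, end),
    )
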