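"""Gene models and splice-site detection.

A :class:`GeneModel` is a genomic locus with exon structure: the locus
sequence (always stored as the + strand of the locus), the transcribed
strand, ordered exon intervals and an optional CDS. Coordinates are 0-based
half-open in locus space; GFF3 I/O converts from 1-based inclusive.

Splice sites are the canonical intron-terminal dinucleotides: each intron
starts with the donor GT and ends with the acceptor AG on the transcribed
strand. Disrupting either dinucleotide base abolishes the signal and causes
exon skipping, which is what splice-targeting guides exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from ._seq import revcomp

Interval = tuple[int, int]


def mirror_interval(iv: Interval, length: int) -> Interval:
    """Mirror a 0-based half-open interval onto the reverse complement."""
    return (length - iv[1], length - iv[0])


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with exon/CDS structure.

    ``exons`` and ``cds`` are sorted, non-overlapping 0-based half-open
    intervals in locus coordinates regardless of strand; ``strand`` says
    which locus strand is transcribed.
    """

    id: str
    sequence: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        seq = self.sequence.upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"gene {self.id}: sequence has non-ACGTN characters")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        if self.cds is not None:
            object.__setattr__(self, "cds", tuple(tuple(c) for c in self.cds))
        self._validate_intervals(self.exons, "exons")
        if self.cds:
            self._validate_intervals(self.cds, "cds")
            for c in self.cds:
                if not any(e[0] <= c[0] and c[1] <= e[1] for e in self.exons):
                    raise ValueError(f"gene {self.id}: CDS {c} not contained in any exon")

    def _validate_intervals(self, ivs: tuple[Interval, ...], what: str) -> None:
        L = len(self.sequence)
        prev_end = -1
        for s, e in ivs:
            if not (0 <= s < e <= L):
                raise ValueError(f"gene {self.id}: {what} interval ({s},{e}) out of bounds")
            if s < prev_end:
                raise ValueError(f"gene {self.id}: {what} overlap or unsorted at ({s},{e})")
            prev_end = e

    # -- strand handling -------------------------------------------------

    def coding_view(self) -> "GeneModel":
        """The gene re-expressed so the transcribed strand is the + strand.

        For + genes this is the model itself; for - genes the sequence is
        reverse-complemented and all intervals mirrored. Designing in this
        view and mirroring results back gives exact strand symmetry.
        """
        if self.strand == "+":
            return self
        L = len(self.sequence)
        return GeneModel(
            id=self.id,
            sequence=revcomp(self.sequence),
            strand="+",
            exons=tuple(sorted(mirror_interval(e, L) for e in self.exons)),
            cds=(
                tuple(sorted(mirror_interval(c, L) for c in self.cds))
                if self.cds
                else None
            ),
        )

    def cds_sequence(self) -> str:
        """Spliced CDS on the coding strand (first base = initiator A of ATG)."""
        if not self.cds:
            raise ValueError(f"gene {self.id} has no CDS")
        cg = self.coding_view()
        return "".join(cg.sequence[s:e] for s, e in cg.cds)

    def cds_positions(self) -> list[int]:
        """Coding-view locus position of every CDS base, in CDS order."""
        cg = self.coding_view()
        out: list[int] = []
        for s, e in cg.cds:
            out.extend(range(s, e))
        return out


@dataclass(frozen=True)
class SpliceSite:
    """An intronic splice-signal dinucleotide (GT donor / AG acceptor)."""

    kind: str  # "donor" | "acceptor"
    positions: tuple[int, int]  # locus coordinates of the two bases, ascending
    flanking_exon: int  # exon index (donor: upstream exon; acceptor: downstream)
    dinucleotide: str  # as read on the transcribed strand
    canonical: bool

    def __post_init__(self) -> None:
        if self.kind not in ("donor", "acceptor"):
            raise ValueError(f"kind must be donor/acceptor, got {self.kind!r}")


def _splice_sites_coding(cg: GeneModel) -> list[tuple[str, tuple[int, int], int, str]]:
    """(kind, coding positions, exon index, dinucleotide) in coding view."""
    sites = []
    n = len(cg.exons)
    for j, (s, e) in enumerate(cg.exons):
        if j < n - 1:  # donor: first two intronic bases after the exon
            sites.append(("donor", (e, e + 1), j, cg.sequence[e : e + 2]))
        if j > 0:  # acceptor: last two intronic bases before the exon
            sites.append(("acceptor", (s - 2, s - 1), j, cg.sequence[s - 2 : s]))
    return sites


_CANON = {"donor": "GT", "acceptor": "AG"}


def find_splice_sites(gene: GeneModel, include_noncanonical: bool = False) -> list[SpliceSite]:
    """Donor/acceptor dinucleotides of every intron, in locus coordinates.

    Non-canonical dinucleotides (anything but GT donor / AG acceptor on
    the transcribed strand) are flagged and excluded unless
    ``include_noncanonical`` is set. A single-exon gene yields [].
    """
    cg = gene.coding_view()
    L = len(gene.sequence)
    out = []
    for kind, (p0, p1), exon_idx, dinuc in _splice_sites_coding(cg):
        canonical = dinuc == _CANON[kind]
        if not canonical and not include_noncanonical:
            continue
        if gene.strand == "+":
            positions = (p0, p1)
        else:
            positions = (L - 1 - p1, L - 1 - p0)
        out.append(SpliceSite(kind, positions, exon_idx, dinuc, canonical))
    return out
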