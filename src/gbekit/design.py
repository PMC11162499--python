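"""sgRNA candidate enumeration and classification.

Implements the design calculus for editing-window-constrained base editors:
enumerate every PAM-valid 20-nt protospacer on either strand of a locus,
then keep the placements where a targetable base (a splice-signal
dinucleotide base, a codon base whose edit creates a stop, or a premature
stop whose edit restores a sense codon) sits inside the editor's editing
window on the protospacer strand.

Protospacer positions are 1-based with the PAM at 21-23. Loci use 0-based
half-open coordinates. Minus-strand gene models are designed in their
coding view and results are mirrored back, which makes designs exactly
strand-symmetric.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from ._seq import (
    DNA,
    IUPAC,
    complement,
    matches_iupac,
    revcomp,
    translate_codon,
    validate_iupac_pattern,
)
from .editors import EditorSpec, can_edit
from .genes import GeneModel, SpliceSite, _splice_sites_coding, _CANON, mirror_interval

PROTOSPACER_LEN = 20
FRAME_LEN = 23  # protospacer + PAM

APPLICATIONS = (
    "SD_disruption",
    "SA_disruption",
    "PTC_introduction",
    "PTC_bypass",
    "reporter_restoration",
)


class ProtospacerFrame(NamedTuple):
    protospacer: str  # 20 nt, protospacer-strand sense
    pam: str  # 3 nt, protospacer-strand sense
    interval: tuple[int, int]  # 0-based half-open locus interval of the 23-nt frame
    strand: str  # '+' | '-' relative to the locus


@dataclass
class GuideCandidate:
    """One protospacer placement valid for one application with one editor."""

    protospacer: str
    pam: str
    interval: tuple[int, int]
    guide_strand: str
    targeted_base_position: int  # 1-based protospacer position of the edited base
    targeted_locus_position: int  # locus coordinate of that base
    source_base: str  # base edited, read on the protospacer strand
    intended_products: tuple[str, ...]  # product bases on the protospacer strand
    application: str
    editors: frozenset = field(default_factory=frozenset)
    gene_id: str | None = None
    site_kind: str | None = None
    outcomes: tuple = ()  # (edited_codon, amino_acid_or_stop) for codon applications

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if self.application not in APPLICATIONS:
            raise ValueError(f"unknown application {self.application!r}")

    @property
    def key(self) -> tuple:
        """Candidate identity used for cross-editor comparison."""
        return (self.protospacer, self.interval, self.guide_strand)


# ---------------------------------------------------------------------------
# protospacer scanning
# ---------------------------------------------------------------------------

def scan_protospacers(sequence: str, pam: str = "NGG") -> list[ProtospacerFrame]:
    """Every PAM-valid 23-nt frame on both strands of ``sequence``.

    Frames containing N are excluded. Output is ordered by locus coordinate
    of the frame, + strand before - strand at the same coordinate.
    """
    pam = validate_iupac_pattern(pam)
    sequence = sequence.upper()
    out: list[ProtospacerFrame] = []
    for i in range(len(sequence) - FRAME_LEN + 1):
        frame = sequence[i : i + FRAME_LEN]
        if "N" in frame:
            continue
        if matches_iupac(frame[PROTOSPACER_LEN:], pam):
            out.append(ProtospacerFrame(frame[:PROTOSPACER_LEN], frame[PROTOSPACER_LEN:], (i, i + FRAME_LEN), "+"))
        rc = revcomp(frame)
        if matches_iupac(rc[PROTOSPACER_LEN:], pam):
            out.append(ProtospacerFrame(rc[:PROTOSPACER_LEN], rc[PROTOSPACER_LEN:], (i, i + FRAME_LEN), "-"))
    return out


def _frame_position(frame: ProtospacerFrame, locus_pos: int) -> int | None:
    """1-based protospacer position of ``locus_pos`` within ``frame``.

    Returns None when the position falls outside positions 1-20 (i.e. in
    the PAM or outside the frame).
    """
    s, e = frame.interval
    if not s <= locus_pos < e:
        return None
    pos = locus_pos - s + 1 if frame.strand == "+" else e - locus_pos
    return pos if pos <= PROTOSPACER_LEN else None


def _strand_base(frame: ProtospacerFrame, base_plus: str) -> str:
    """``base_plus`` (the + strand base) as read on the protospacer strand."""
    return base_plus if frame.strand == "+" else complement(base_plus)


# ---------------------------------------------------------------------------
# splice-site guides
# ---------------------------------------------------------------------------

def _mirror_candidate(c: GuideCandidate, length: int) -> GuideCandidate:
    c.interval = mirror_interval(c.interval, length)
    c.guide_strand = "+" if c.guide_strand == "-" else "-"
    c.targeted_locus_position = length - 1 - c.targeted_locus_position
    return c


def find_splice_site_guides(
    gene: GeneModel,
    editor: EditorSpec,
    mode: str = "optimal",
    pam: str | None = None,
) -> list[GuideCandidate]:
    """Guides that place a splice-signal dinucleotide base in the window.

    For every canonical donor (GT) or acceptor (AG) and every PAM-valid
    frame on either strand, a candidate is emitted per dinucleotide base
    that, read on the protospacer strand, equals the editor's source base
    and sits inside the requested editing window. Any such edit destroys
    the splice signal, so the application is SD_/SA_disruption.
    """
    cg = gene.coding_view()
    frames = scan_protospacers(cg.sequence, pam or editor.pam)
    out: list[GuideCandidate] = []
    for kind, positions, _exon, dinuc in _splice_sites_coding(cg):
        if dinuc != _CANON[kind]:
            continue
        for frame in frames:
            for p in positions:
                pos = _frame_position(frame, p)
                if pos is None:
                    continue
                base = _strand_base(frame, cg.sequence[p])
                if not can_edit(editor, base, pos, mode):
                    continue
                out.append(
                    GuideCandidate(
                        protospacer=frame.protospacer,
                        pam=frame.pam,
                        interval=frame.interval,
                        guide_strand=frame.strand,
                        targeted_base_position=pos,
                        targeted_locus_position=p,
                        source_base=base,
                        intended_products=editor.conversion.design_products,
                        application="SD_disruption" if kind == "donor" else "SA_disruption",
                        editors=frozenset({editor.name}),
                        gene_id=gene.id,
                        site_kind=kind,
                    )
                )
    if gene.strand == "-":
        out = [_mirror_candidate(c, len(gene.sequence)) for c in out]
    out.sort(key=lambda c: (c.interval, c.guide_strand, c.targeted_base_position))
    return out


# ---------------------------------------------------------------------------
# codon editing
# ---------------------------------------------------------------------------

def codon_edit_outcomes(
    codon: str,
    editor: EditorSpec,
    include_minor: bool = False,
) -> set[tuple[str, str, str]]:
    """All single-base codon edits reachable by the editor's chemistry.

    Both codon strands are exposed: an edit on the antisense strand
    complements back into the sense codon. Returns
    ``{(edited_codon, amino_acid_or_'*', protospacer_strand)}`` where the
    strand is '+' (sense) or '-' (antisense) relative to the codon.
    """
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set(DNA):
        raise ValueError(f"invalid codon {codon!r}")
    conv = editor.conversion
    products = conv.product_bases if include_minor else conv.design_products
    out: set[tuple[str, str, str]] = set()
    for strand in "+-":
        for i, sense_base in enumerate(codon):
            base = sense_base if strand == "+" else complement(sense_base)
            if base != conv.source_base:
                continue
            for product in products:
                new_sense = product if strand == "+" else complement(product)
                edited = codon[:i] + new_sense + codon[i + 1 :]
                out.add((edited, translate_codon(edited), strand))
    return out


def _codon_guides(
    gene: GeneModel,
    editor: EditorSpec,
    mode: str,
    pam: str | None,
    codon_filter,
    outcome_filter,
    application: str,
) -> list[GuideCandidate]:
    """Shared machinery for PTC introduction / bypass guide enumeration.

    ``codon_filter(index, codon)`` selects which CDS codons to consider;
    ``outcome_filter(aa)`` selects which edited-codon translations count
    as a hit for the application.
    """
    if not gene.cds:
        raise ValueError(f"gene {gene.id} has no CDS")
    cg = gene.coding_view()
    cds_seq = gene.cds_sequence()
    cds_pos = gene.cds_positions()
    frames = scan_protospacers(cg.sequence, pam or editor.pam)
    frames_by_strand = {"+": [f for f in frames if f.strand == "+"],
                        "-": [f for f in frames if f.strand == "-"]}
    out: list[GuideCandidate] = []
    n_codons = len(cds_seq) // 3
    for k in range(n_codons):
        codon = cds_seq[3 * k : 3 * k + 3]
        if not codon_filter(k, codon):
            continue
        # group stop/sense-producing edits by (edited base offset, strand)
        edits: dict[tuple[int, str], list[tuple[str, str]]] = {}
        conv = editor.conversion
        for strand in "+-":
            for i, sense_base in enumerate(codon):
                base = sense_base if strand == "+" else complement(sense_base)
                if base != conv.source_base:
                    continue
                for product in conv.design_products:
                    new_sense = product if strand == "+" else complement(product)
                    edited = codon[:i] + new_sense + codon[i + 1 :]
                    aa = translate_codon(edited)
                    if outcome_filter(aa):
                        edits.setdefault((i, strand), []).append((edited, aa))
        for (i, strand), outcomes in edits.items():
            p = cds_pos[3 * k + i]
            for frame in frames_by_strand[strand]:
                pos = _frame_position(frame, p)
                if pos is None:
                    continue
                base = _strand_base(frame, cg.sequence[p])
                if not can_edit(editor, base, pos, mode):
                    continue
                out.append(
                    GuideCandidate(
                        protospacer=frame.protospacer,
                        pam=frame.pam,
                        interval=frame.interval,
                        guide_strand=frame.strand,
                        targeted_base_position=pos,
                        targeted_locus_position=p,
                        source_base=base,
                        intended_products=conv.design_products,
                        application=application,
                        editors=frozenset({editor.name}),
                        gene_id=gene.id,
                        outcomes=tuple(sorted(set(outcomes))),
                    )
                )
    if gene.strand == "-":
        out = [_mirror_candidate(c, len(gene.sequence)) for c in out]
    out.sort(key=lambda c: (c.interval, c.guide_strand, c.targeted_base_position))
    return out


def find_ptc_introduction_guides(
    gene: GeneModel,
    editor: EditorSpec,
    mode: str = "optimal",
    pam: str | None = None,
) -> list[GuideCandidate]:
    """Guides whose edit turns a sense codon into a premature stop.

    The initiator codon and the natural stop are never targeted. An edit on
    the antisense strand counts (e.g. CBE converting the antisense CCA of a
    TGG codon yields TGA/TAG).
    """
    n_codons = len(gene.cds_sequence()) // 3 if gene.cds else 0

    def codon_filter(k: int, codon: str) -> bool:
        return 0 < k < n_codons - 1 and translate_codon(codon) != "*"

    return _codon_guides(
        gene, editor, mode, pam, codon_filter, lambda aa: aa == "*", "PTC_introduction"
    )


def find_ptc_bypass_guides(
    gene: GeneModel,
    ptc_codon_index: int,
    editor: EditorSpec,
    mode: str = "optimal",
    pam: str | None = None,
) -> list[GuideCandidate]:
    """Guides converting an annotated premature stop back to a sense codon.

    ``ptc_codon_index`` is the 0-based codon index within the CDS; the
    codon there must be TAA/TAG/TGA. Each candidate lists every reachable
    sense-codon outcome with its amino acid; edits that leave a stop in
    place are not counted.
    """
    cds_seq = gene.cds_sequence()
    codon = cds_seq[3 * ptc_codon_index : 3 * ptc_codon_index + 3]
    if translate_codon(codon) != "*":
        raise ValueError(
            f"codon {ptc_codon_index} of gene {gene.id} is {codon}, not a stop"
        )

    def codon_filter(k: int, _codon: str) -> bool:
        return k == ptc_codon_index

    return _codon_guides(
        gene, editor, mode, pam, codon_filter, lambda aa: aa != "*", "PTC_bypass"
    )


# ---------------------------------------------------------------------------
# reporter restoration
# ---------------------------------------------------------------------------

def predict_reporter_restoration(
    sa_context: str,
    mutated_position: int,
    editor: EditorSpec,
    guide: GuideCandidate,
) -> bool:
    """Can the editor restore an inactivated AG splice acceptor?

    ``sa_context`` is the + strand of the reporter locus around the broken
    acceptor; ``mutated_position`` is the locus coordinate of the mutated
    second acceptor base (the G of AG mutated to T or C). True iff some
    design-time product of the editor's chemistry, applied at that base on
    the guide's protospacer strand, re-creates the G and hence the AG
    signal — the T-to-G / C-to-G reporter-activation logic.
    """
    s, e = guide.interval
    if not s <= mutated_position < e:
        raise ValueError("guide does not cover the mutated base")
    frame = ProtospacerFrame(guide.protospacer, guide.pam, guide.interval, guide.guide_strand)
    pos = _frame_position(frame, mutated_position)
    if pos is None:
        raise ValueError("mutated base falls in the PAM, not the protospacer")
    base = _strand_base(frame, sa_context[mutated_position].upper())
    if base != editor.conversion.source_base:
        return False
    for product in editor.conversion.design_products:
        restored = product if guide.guide_strand == "+" else complement(product)
        if restored == "G":
            return True
    return False


# ---------------------------------------------------------------------------
# cross-editor classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VennPartition:
    """Disjoint-region decomposition of per-editor candidate sets."""

    sets: Mapping[str, frozenset]
    region_counts: Mapping[frozenset, int]  # membership pattern -> count

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def exclusive(self, editor: str) -> int:
        return self.region_counts.get(frozenset({editor}), 0)

    def overlap(self, *editors: str) -> int:
        """Candidates shared by all the named editors (any further membership)."""
        want = set(editors)
        return sum(
            n for pattern, n in self.region_counts.items() if want <= pattern
        )

    def to_dict(self) -> dict:
        return {
            "set_sizes": {k: len(v) for k, v in self.sets.items()},
            "union_size": self.union_size,
            "regions": {
                "&".join(sorted(pattern)): n
                for pattern, n in sorted(
                    self.region_counts.items(), key=lambda kv: sorted(kv[0])
                )
            },
        }


def classify_across_editors(
    candidate_sets: Mapping[str, Iterable[GuideCandidate]],
) -> VennPartition:
    """Partition candidates by which editors can use them.

    Candidate identity is (protospacer, locus interval, guide strand); an
    sgRNA belongs to an editor's set if that editor emitted it for at least
    one targetable base.
    """
    sets = {
        name: frozenset(c.key for c in cands) for name, cands in candidate_sets.items()
    }
    membership: Counter = Counter()
    union = set().union(*sets.values()) if sets else set()
    for key in union:
        pattern = frozenset(name for name, s in sets.items() if key in s)
        membership[pattern] += 1
    return VennPartition(sets=sets, region_counts=dict(membership))


# ---------------------------------------------------------------------------
# naive off-target scan
# ---------------------------------------------------------------------------

def find_offtargets(
    genome_seq: str,
    protospacer: str,
    pam: str = "NGG",
    max_mismatches: int = 3,
) -> list[tuple[tuple[int, int], str, int]]:
    """Hamming-distance off-target scan (no bulges).

    Every PAM-valid 23-nt frame on either strand whose 20-nt protospacer
    differs from ``protospacer`` at <= ``max_mismatches`` positions is
    reported as ``(frame interval, strand, mismatch_count)``; the PAM is
    excluded from the distance.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    protospacer = protospacer.upper()
    if len(protospacer) != PROTOSPACER_LEN:
        raise ValueError("protospacer must be 20 nt")
    out = []
    for frame in scan_protospacers(genome_seq, pam):
        mm = sum(a != b for a, b in zip(frame.protospacer, protospacer))
        if mm <= max_mismatches:
            out.append((frame.interval, frame.strand, mm))
    return out


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def candidates_to_frame(candidates: Sequence[GuideCandidate]):
    """Candidate table mirroring the supplementary-data column idiom."""
    import pandas as pd

    rows = [
        {
            "gene": c.gene_id,
            "application": c.application,
            "site_kind": c.site_kind,
            "protospacer": c.protospacer,
            "pam": c.pam,
            "start": c.interval[0],
            "end": c.interval[1],
            "strand": c.guide_strand,
            "targeted_position": c.targeted_base_position,
            "source_base": c.source_base,
            "intended_products": ",".join(c.intended_products),
            "editors": ",".join(sorted(c.editors)),
            "outcomes": ";".join(f"{cod}>{aa}" for cod, aa in c.outcomes),
        }
        for c in candidates
    ]
    columns = [
        "gene", "application", "site_kind", "protospacer", "pam", "start", "end",
        "strand", "targeted_position", "source_base", "intended_products",
        "editors", "outcomes",
    ]
    return pd.DataFrame(rows, columns=columns)
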