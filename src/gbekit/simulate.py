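"""Synthetic amplicon reads and toy gene models with known ground truth.

Two generators cover everything the pipeline consumes:

* :func:`simulate_amplicon_reads` draws reads from an
  :class:`OutcomeModel` — per-position substitution probabilities around a
  protospacer, an indel mixture and a uniform sequencing-error overlay —
  and returns a per-read ground-truth ledger, so estimator recovery can be
  checked against the generating parameters.
* :func:`simulate_gene_model` builds toy multi-exon genes with canonical
  GT/AG introns, a clean reading frame, optionally a planted premature
  stop codon and planted NGG PAM placements that put a chosen splice-site
  base at a chosen protospacer position.

Everything is deterministic under a fixed seed. Reads carry at most one
indel, and indel reads carry no programmed substitutions: edited outcomes
and indel outcomes are disjoint classes, mirroring how editing results are
reported (conversion fractions vs. indel fractions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import DNA, revcomp
from .genes import GeneModel, mirror_interval

_SENSE_CODONS = tuple(
    a + b + c
    for a in DNA
    for b in DNA
    for c in DNA
    if a + b + c not in ("TAA", "TAG", "TGA")
)


@dataclass(frozen=True)
class OutcomeModel:
    """Ground-truth editing-outcome distribution for one amplicon.

    ``substitution_probs`` maps a 0-based reference position to
    ``{product_base: probability}``; probabilities at a position must sum
    to <= 1 (the remainder is the unedited outcome). ``indel_lengths`` are
    signed (negative = deletion of that many bases, positive = insertion),
    drawn uniformly; the event start is uniform over the quantification
    window (protospacer +/- flank). ``sequencing_error_rate`` is the
    per-base uniform miscall probability overlaid on every read.
    """

    reference: str
    protospacer_interval: tuple[int, int]
    substitution_probs: dict[int, dict[str, float]] = field(default_factory=dict)
    indel_probability: float = 0.0
    indel_lengths: tuple[int, ...] = (-3, -2, -1, 1)
    sequencing_error_rate: float = 0.0
    quantification_flank: int = 3

    def __post_init__(self) -> None:
        ref = self.reference.upper()
        object.__setattr__(self, "reference", ref)
        ps, pe = self.protospacer_interval
        if not 0 <= ps < pe <= len(ref):
            raise ValueError("protospacer_interval outside reference")
        for pos, probs in self.substitution_probs.items():
            if not 0 <= pos < len(ref):
                raise ValueError(f"substitution position {pos} outside reference")
            total = 0.0
            for base, p in probs.items():
                if base not in DNA or base == ref[pos]:
                    raise ValueError(f"invalid product {base!r} at position {pos}")
                if not 0 <= p <= 1:
                    raise ValueError(f"probability {p} out of [0,1]")
                total += p
            if total > 1 + 1e-12:
                raise ValueError(f"substitution probabilities at {pos} sum to {total} > 1")
        if not 0 <= self.indel_probability <= 1:
            raise ValueError("indel_probability must be in [0,1]")
        if any(l == 0 for l in self.indel_lengths):
            raise ValueError("indel lengths must be nonzero")
        if not 0 <= self.sequencing_error_rate <= 1:
            raise ValueError("sequencing_error_rate must be in [0,1]")

    @classmethod
    def for_protospacer(
        cls,
        reference: str,
        protospacer_interval: tuple[int, int],
        protospacer_probs: dict[int, dict[str, float]],
        **kwargs,
    ) -> "OutcomeModel":
        """Build a model keyed by 1-based protospacer positions instead."""
        ps = protospacer_interval[0]
        return cls(
            reference=reference,
            protospacer_interval=protospacer_interval,
            substitution_probs={
                ps + pos - 1: dict(probs) for pos, probs in protospacer_probs.items()
            },
            **kwargs,
        )


def simulate_amplicon_reads(
    model: OutcomeModel, n: int, seed: int | np.random.Generator = 0
) -> tuple[list[str], list[dict]]:
    """Draw ``n`` reads from ``model``; returns (reads, per-read ledger).

    Each read independently either carries one indel (probability
    ``indel_probability``, start uniform in the quantification window) or
    carries per-position substitutions; uniform sequencing error is then
    overlaid on all reads. The ledger records the true event of each read.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref = model.reference
    L = len(ref)
    ps, pe = model.protospacer_interval
    ws = max(0, ps - model.quantification_flank)
    we = min(L, pe + model.quantification_flank)
    sub_items = sorted(
        (pos, tuple(probs.items())) for pos, probs in model.substitution_probs.items()
    )

    reads: list[str] = []
    ledger: list[dict] = []
    for _ in range(n):
        entry: dict = {"indel": None, "substitutions": {}, "n_errors": 0}
        if model.indel_probability and rng.random() < model.indel_probability:
            length = int(model.indel_lengths[rng.integers(len(model.indel_lengths))])
            if length < 0:
                start = int(rng.integers(ws, min(we, L + length)))
                read = ref[:start] + ref[start - length :]
            else:
                start = int(rng.integers(ws, we))
                insert = "".join(DNA[i] for i in rng.integers(0, 4, size=length))
                read = ref[:start] + insert + ref[start:]
            entry["indel"] = (start, length)
        else:
            bases = list(ref)
            for pos, probs in sub_items:
                u = rng.random()
                acc = 0.0
                for base, p in probs:
                    acc += p
                    if u < acc:
                        bases[pos] = base
                        entry["substitutions"][pos] = base
                        break
            read = "".join(bases)
        if model.sequencing_error_rate:
            err = rng.random(len(read)) < model.sequencing_error_rate
            if err.any():
                bases = list(read)
                for i in np.flatnonzero(err):
                    choices = [b for b in DNA if b != bases[i]]
                    bases[i] = choices[rng.integers(3)]
                    entry["n_errors"] += 1
                read = "".join(bases)
        reads.append(read)
        ledger.append(entry)
    return reads, ledger


def random_amplicon(
    rng: np.random.Generator,
    length: int = 60,
    protospacer_start: int = 20,
    source_base: str | None = None,
    ensure_positions: tuple[int, ...] = (),
) -> tuple[str, tuple[int, int]]:
    """Random amplicon with a protospacer at a fixed offset.

    ``ensure_positions`` forces the reference base at those 1-based
    protospacer positions to ``source_base`` so that per-position editing
    statistics are defined there.
    """
    bases = [DNA[i] for i in rng.integers(0, 4, size=length)]
    for pos in ensure_positions:
        bases[protospacer_start + pos - 1] = source_base
    return "".join(bases), (protospacer_start, protospacer_start + 20)


# ---------------------------------------------------------------------------
# toy gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedGuide:
    """Request to plant an NGG PAM placing a splice-site base in a window.

    ``site_index`` indexes the donors (kind="donor") or acceptors
    (kind="acceptor") in transcription order; ``dinucleotide_base`` is 0
    (G of GT / A of AG) or 1 (T of GT / G of AG);
    ``protospacer_position`` is where that base must sit (1-based, + strand
    guide in coding orientation).
    """

    kind: str = "donor"
    site_index: int = 0
    dinucleotide_base: int = 1
    protospacer_position: int = 5


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the toy-gene generator."""

    n_exons: int = 3
    exon_codons: tuple[int, int] = (20, 40)  # codons per exon (min, max)
    intron_length: tuple[int, int] = (60, 120)
    strand: str = "+"
    planted_ptc: str | None = None  # stop codon planted mid-CDS, e.g. "TAG"
    planted_guides: tuple[PlantedGuide, ...] = ()
    pam_free: bool = False  # background free of NGG PAMs on both strands

    def __post_init__(self) -> None:
        if self.n_exons < 2:
            raise ValueError("need >= 2 exons")
        if self.planted_ptc is not None and self.planted_ptc not in ("TAA", "TAG", "TGA"):
            raise ValueError("planted_ptc must be a stop codon")
        if self.intron_length[0] < 30:
            raise ValueError("introns must be >= 30 bp to leave room for planted PAMs")
        if self.pam_free and self.planted_guides:
            raise ValueError("cannot plant PAMs in a PAM-free background")


def _pam_free_sequence(rng: np.random.Generator, length: int, forced: dict[int, str]) -> list[str]:
    """Sequence with no GG or CC dinucleotide (hence no NGG PAM on either strand).

    ``forced`` pins characters (splice dinucleotides); random characters
    avoid completing GG/CC with their neighbours, with one-step lookahead
    onto forced positions.
    """
    out: list[str] = []
    for i in range(length):
        if i in forced:
            c = forced[i]
            if out and out[-1] == c and c in "GC":
                raise ValueError(f"forced base at {i} would create {c}{c}")
        else:
            banned = set()
            if out and out[-1] in "GC":
                banned.add(out[-1])
            nxt = forced.get(i + 1)
            if nxt in ("G", "C"):
                banned.add(nxt)
            choices = [b for b in DNA if b not in banned]
            c = choices[rng.integers(len(choices))]
        out.append(c)
    return out


def simulate_gene_model(
    config: SimConfig, seed: int | np.random.Generator = 0
) -> tuple[GeneModel, dict]:
    """Toy gene with canonical splice sites; returns (gene, ground-truth ledger).

    The CDS spans all exons in frame: ATG, random sense codons, terminal
    TAA. A planted PTC replaces the codon midway through the CDS. Planted
    guides overwrite intron interior bases with an AGG PAM so the requested
    splice-site base lands at the requested protospacer position. In
    ``pam_free`` mode the locus contains no NGG PAM on either strand and no
    CDS is annotated (the background is not constrained to sense codons).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    exon_lens = [
        3 * int(rng.integers(config.exon_codons[0], config.exon_codons[1] + 1))
        for _ in range(config.n_exons)
    ]
    intron_lens = [
        int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
        for _ in range(config.n_exons - 1)
    ]

    # exon/intron layout in coding orientation
    exons: list[tuple[int, int]] = []
    pos = 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    L = pos

    donors = [(e, e + 1) for (_, e) in exons[:-1]]
    acceptors = [(s - 2, s - 1) for (s, _) in exons[1:]]

    ptc_index = None
    if config.pam_free:
        forced: dict[int, str] = {}
        for d0, d1 in donors:
            forced[d0], forced[d1] = "G", "T"
        for a0, a1 in acceptors:
            forced[a0], forced[a1] = "A", "G"
        seq = _pam_free_sequence(rng, L, forced)
        cds = None
    else:
        n_codons = sum(exon_lens) // 3
        codons = ["ATG"]
        codons += [
            _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))] for _ in range(n_codons - 2)
        ]
        codons.append("TAA")
        if config.planted_ptc is not None:
            ptc_index = n_codons // 2
            codons[ptc_index] = config.planted_ptc
        cds_seq = "".join(codons)
        seq = [DNA[i] for i in rng.integers(0, 4, size=L)]
        k = 0
        for s, e in exons:
            seq[s:e] = cds_seq[k : k + (e - s)]
            k += e - s
        for d0, d1 in donors:
            seq[d0], seq[d1] = "G", "T"
        for a0, a1 in acceptors:
            seq[a0], seq[a1] = "A", "G"
        cds = tuple(exons)

    planted = []
    for pg in config.planted_guides:
        sites = donors if pg.kind == "donor" else acceptors
        target = sites[pg.site_index][pg.dinucleotide_base]
        frame_start = target - (pg.protospacer_position - 1)
        pam_start = frame_start + 20
        if frame_start < 0 or pam_start + 3 > L:
            raise ValueError(f"planted guide {pg} falls outside the locus")
        site_pair = sites[pg.site_index]
        protected = set(range(site_pair[0] - 2, site_pair[1] + 3))
        if any(p in protected for p in range(pam_start, pam_start + 3)):
            raise ValueError(f"planted PAM for {pg} would overwrite the splice signal")
        seq[pam_start : pam_start + 3] = list("AGG")
        planted.append(
            {
                "kind": pg.kind,
                "site_index": pg.site_index,
                "targeted_position": target,
                "protospacer_position": pg.protospacer_position,
                "frame": (frame_start, frame_start + 23),
                "strand": "+",
            }
        )

    sequence = "".join(seq)
    ledger = {
        "strand": config.strand,
        "exons": list(exons),
        "splice_sites": (
            [("donor", d) for d in donors] + [("acceptor", a) for a in acceptors]
        ),
        "ptc_codon_index": ptc_index,
        "planted_guides": planted,
    }

    if config.strand == "-":
        # express the same gene on the minus strand of a mirrored locus
        sequence = revcomp(sequence)
        exons_m = tuple(sorted(mirror_interval(e, L) for e in exons))
        cds_m = tuple(sorted(mirror_interval(c, L) for c in cds)) if cds else None
        gene = GeneModel("simgene", sequence, "-", exons_m, cds_m)
        ledger["splice_sites"] = [
            (kind, (L - 1 - p1, L - 1 - p0)) for kind, (p0, p1) in ledger["splice_sites"]
        ]
        ledger["exons"] = [mirror_interval(e, L) for e in exons]
    else:
        gene = GeneModel("simgene", sequence, "+", tuple(exons), cds)
    return gene, ledger
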