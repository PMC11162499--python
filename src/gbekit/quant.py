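"""Amplicon deep-sequencing outcome quantification.

Reads from an edited amplicon are globally aligned to the reference and
tallied per reference position into A/C/G/T/deletion counts, from which the
editing statistics used to characterise base editors are derived:

* per-position conversion frequencies, under two denominators — over all
  reads (``with_indels``) or over reads without an indel in the
  quantification window (``without_indels``);
* indel frequency: the fraction of reads with any insertion or deletion
  overlapping the protospacer +/- a flank;
* product purity, e.g. T-to-G purity = T→G yield / T→(A+C+G) yield;
* the T-to-S conversion ratio = T→(C+G) yield / T→(A+C+G) yield
  (S = strong bases C/G);
* editing-window profiles across protospacer positions 1-20 and 5'-motif
  preference across sites.

The reference is taken protospacer-strand sense, so protospacer position p
(1-based) is reference position ``protospacer_start + p - 1``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

BASES = "ACGT"
DEL = 4  # row index of the deletion call
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap global alignment scores plus the indel-counting flank."""

    match_score: float = 2.0
    mismatch_penalty: float = -2.0
    gap_open: float = -10.0
    gap_extend: float = -1.0
    quantification_flank: int = 3

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0 <= self.match_score):
            raise ValueError("require gap_open <= gap_extend <= 0 <= match_score")
        if self.mismatch_penalty > 0:
            raise ValueError("mismatch_penalty must be <= 0")
        if self.quantification_flank < 0:
            raise ValueError("quantification_flank must be >= 0")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = self.match_score
        a.mismatch_score = self.mismatch_penalty
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        return a


@dataclass
class AlignedRead:
    """Per-reference-position calls for one read."""

    calls: list[str]  # base or "-" (deletion) for every reference position
    insertions: list[tuple[int, str]]  # (reference gap position, inserted seq)

    @property
    def has_gap(self) -> bool:
        return bool(self.insertions) or "-" in self.calls

    def gap_overlaps(self, start: int, end: int) -> bool:
        """Any deletion column or insertion point inside [start, end)."""
        if any(self.calls[i] == "-" for i in range(start, end)):
            return True
        return any(start <= g <= end for g, _ in self.insertions)


def align_read(read: str, reference: str, params: AlignmentParams | None = None) -> AlignedRead:
    """Globally align ``read`` to ``reference`` with affine gap scores.

    Tie-breaking is deterministic: the aligner's first optimal alignment is
    used. Equal-length identical reads short-circuit without alignment.
    """
    if not read or not reference:
        raise ValueError("read and reference must be non-empty")
    read, reference = read.upper(), reference.upper()
    if read == reference:
        return AlignedRead(calls=list(reference), insertions=[])
    aln = (params or AlignmentParams()).aligner().align(reference, read)[0]
    calls = ["-"] * len(reference)
    insertions: list[tuple[int, str]] = []
    t_blocks, q_blocks = aln.aligned
    prev_t_end = prev_q_end = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if qs > prev_q_end:  # query advanced with no target: insertion
            insertions.append((ts, read[prev_q_end:qs]))
        for t, q in zip(range(ts, te), range(qs, qe)):
            calls[t] = read[q]
        prev_t_end, prev_q_end = te, qe
    if prev_q_end < len(read):  # trailing insertion past the reference end
        insertions.append((len(reference), read[prev_q_end:]))
    return AlignedRead(calls=calls, insertions=insertions)


@dataclass
class AmpliconOutcomeTable:
    """Per-position outcome counts over the aligned reads of one amplicon."""

    reference: str
    protospacer_interval: tuple[int, int]
    counts: np.ndarray  # (L, 5) A/C/G/T/deletion over all reads
    counts_noindel: np.ndarray  # same, restricted to reads without an indel
    insertions: Counter  # reference gap position -> count (indel reads)
    n_reads_total: int
    n_reads_indel: int
    n_reads_discarded: int = 0
    quantification_flank: int = 3

    def ref_position(self, protospacer_position: int) -> int:
        """Reference coordinate of a 1-based protospacer position."""
        if not 1 <= protospacer_position <= 20:
            raise ValueError("protospacer position must be in 1..20")
        return self.protospacer_interval[0] + protospacer_position - 1

    def _matrix(self, denominator: str) -> np.ndarray:
        if denominator == "with_indels":
            return self.counts
        if denominator == "without_indels":
            return self.counts_noindel
        raise ValueError(f"denominator must be with_indels/without_indels, got {denominator!r}")

    def frequency(self, position: int, product: str, denominator: str = "without_indels") -> float:
        """Fraction of reads calling ``product`` at reference ``position``."""
        m = self._matrix(denominator)
        total = m[position].sum()
        if total == 0:
            return math.nan
        row = DEL if product in ("-", "del") else _BASE_INDEX[product]
        return float(m[position, row] / total)


def quantify_amplicon(
    reads: Iterable[str],
    reference: str,
    protospacer_interval: tuple[int, int],
    params: AlignmentParams | None = None,
) -> AmpliconOutcomeTable:
    """Align and tally reads into an :class:`AmpliconOutcomeTable`.

    A read is an *indel read* iff any gap event overlaps the quantification
    window (protospacer +/- ``quantification_flank``). Reads shorter than
    that window are discarded (counted in ``n_reads_discarded``).
    Equal-length reads with no gaps take a direct column-compare fast path;
    anything else goes through the affine-gap aligner. Duplicate read
    strings are independent observations and each counts once.
    """
    params = params or AlignmentParams()
    reference = reference.upper()
    L = len(reference)
    ps, pe = protospacer_interval
    if not 0 <= ps < pe <= L:
        raise ValueError("protospacer_interval outside reference")
    ws = max(0, ps - params.quantification_flank)
    we = min(L, pe + params.quantification_flank)

    counts = np.zeros((L, 5), dtype=np.int64)
    counts_noindel = np.zeros((L, 5), dtype=np.int64)
    insertions: Counter = Counter()
    n_total = n_indel = n_discarded = 0

    for read in reads:
        read = read.upper()
        if len(read) < we - ws:
            n_discarded += 1
            continue
        n_total += 1
        if len(read) == L:  # no-gap fast path (substitutions only)
            aligned = AlignedRead(calls=list(read), insertions=[])
        else:
            aligned = align_read(read, reference, params)
        is_indel = aligned.has_gap and aligned.gap_overlaps(ws, we)
        if is_indel:
            n_indel += 1
            for g, _seq in aligned.insertions:
                insertions[g] += 1
        for i, call in enumerate(aligned.calls):
            row = DEL if call == "-" else _BASE_INDEX.get(call)
            if row is None:  # N or other ambiguity: position uncounted
                continue
            counts[i, row] += 1
            if not is_indel:
                counts_noindel[i, row] += 1

    return AmpliconOutcomeTable(
        reference=reference,
        protospacer_interval=(ps, pe),
        counts=counts,
        counts_noindel=counts_noindel,
        insertions=insertions,
        n_reads_total=n_total,
        n_reads_indel=n_indel,
        n_reads_discarded=n_discarded,
        quantification_flank=params.quantification_flank,
    )


# ---------------------------------------------------------------------------
# derived statistics
# ---------------------------------------------------------------------------

def _product_counts(
    table: AmpliconOutcomeTable, position: int, source_base: str, denominator: str
) -> tuple[np.ndarray, float]:
    if table.reference[position] != source_base:
        raise ValueError(
            f"reference base at {position} is {table.reference[position]}, "
            f"expected {source_base}"
        )
    m = table._matrix(denominator)
    row = m[position].astype(float)
    others = [b for b in BASES if b != source_base]
    den = sum(row[_BASE_INDEX[b]] for b in others)
    if denominator == "with_indels":
        den += row[DEL]
    return row, den


def conversion_purity(
    table: AmpliconOutcomeTable,
    position: int,
    source_base: str = "T",
    product: str = "G",
    denominator: str = "without_indels",
) -> float | None:
    """Product purity: product yield / all-conversion yield at one position.

    E.g. T-to-G purity = T→G / (T→A + T→C + T→G). ``position`` is a
    reference coordinate whose reference base must equal ``source_base``.
    Under ``with_indels`` the deletion calls join the denominator.
    Returns None when no conversion was observed (zero denominator).
    """
    row, den = _product_counts(table, position, source_base, denominator)
    if den == 0:
        return None
    return float(row[_BASE_INDEX[product]] / den)


def conversion_ratio_ts(
    table: AmpliconOutcomeTable,
    position: int,
    source_base: str = "T",
    s_products: tuple[str, ...] = ("C", "G"),
    denominator: str = "without_indels",
) -> float | None:
    """T-to-S ratio: (T→C + T→G) yield / (T→A + T→C + T→G) yield.

    Generalises to any source base and product set (for C editors use
    source C, products G/T as appropriate). Same denominator conventions
    as :func:`conversion_purity`.
    """
    row, den = _product_counts(table, position, source_base, denominator)
    if den == 0:
        return None
    num = sum(row[_BASE_INDEX[b]] for b in s_products)
    return float(num / den)


def indel_frequency(table: AmpliconOutcomeTable) -> float | None:
    """Fraction of reads with a gap event in the quantification window."""
    if table.n_reads_total == 0:
        return None
    return table.n_reads_indel / table.n_reads_total


def fold_change(value_a: float, value_b: float) -> float | None:
    """``value_a / value_b`` rounded to 2 significant figures.

    The convention used when reporting editing-efficiency enhancements
    (e.g. 51.4% over 13.3% is a 3.9-fold enhancement). Returns None for a
    zero baseline.
    """
    if value_b == 0:
        return None
    r = value_a / value_b
    digits = 1 - math.floor(math.log10(abs(r)))
    return round(r, digits)


# ---------------------------------------------------------------------------
# per-site summaries, window profiles, motif preference
# ---------------------------------------------------------------------------

@dataclass
class EditingSummary:
    """Editing statistics of one amplicon site for one source base."""

    source_base: str
    reference: str
    protospacer_interval: tuple[int, int]
    # protospacer position -> product base -> frequency
    conversion_without_indels: dict[int, dict[str, float]]
    conversion_with_indels: dict[int, dict[str, float]]
    indel_frequency: float | None
    peak_position: int | None  # protospacer position with max total conversion
    purity: float | None  # predominant-product purity at the peak
    ts_ratio_without_indels: float | None
    ts_ratio_with_indels: float | None

    def total_conversion(self, position: int, denominator: str = "without_indels") -> float:
        freqs = (
            self.conversion_without_indels
            if denominator == "without_indels"
            else self.conversion_with_indels
        )
        return sum(freqs.get(position, {}).values())


def summarize_editing(
    table: AmpliconOutcomeTable,
    source_base: str = "T",
    s_products: tuple[str, ...] = ("C", "G"),
    purity_product: str = "G",
) -> EditingSummary:
    """Collapse an outcome table into the per-site editing summary.

    Conversion frequencies are reported at every protospacer position whose
    reference base equals ``source_base``. The peak is the position with the
    highest total conversion (without-indel denominator); ties break toward
    the PAM-distal (lower) position.
    """
    ps, pe = table.protospacer_interval
    conv_wo: dict[int, dict[str, float]] = {}
    conv_wi: dict[int, dict[str, float]] = {}
    products = [b for b in BASES if b != source_base]
    for pos in range(1, min(20, pe - ps) + 1):
        ref_i = table.ref_position(pos)
        if table.reference[ref_i] != source_base:
            continue
        conv_wo[pos] = {
            b: table.frequency(ref_i, b, "without_indels") for b in products
        }
        conv_wi[pos] = {b: table.frequency(ref_i, b, "with_indels") for b in products}

    peak = None
    if conv_wo:
        totals = {
            p: sum(0.0 if math.isnan(v) else v for v in d.values())
            for p, d in conv_wo.items()
        }
        peak = min(totals, key=lambda p: (-totals[p], p))

    purity = ts_wo = ts_wi = None
    if peak is not None:
        ref_i = table.ref_position(peak)
        purity = conversion_purity(table, ref_i, source_base, purity_product)
        ts_wo = conversion_ratio_ts(table, ref_i, source_base, s_products, "without_indels")
        ts_wi = conversion_ratio_ts(table, ref_i, source_base, s_products, "with_indels")

    return EditingSummary(
        source_base=source_base,
        reference=table.reference,
        protospacer_interval=table.protospacer_interval,
        conversion_without_indels=conv_wo,
        conversion_with_indels=conv_wi,
        indel_frequency=indel_frequency(table),
        peak_position=peak,
        purity=purity,
        ts_ratio_without_indels=ts_wo,
        ts_ratio_with_indels=ts_wi,
    )


@dataclass
class WindowProfile:
    """Aggregated per-position editing profile across sites."""

    positions: dict[int, dict[str, float]]  # pos -> {median, q1, q3, n}
    peak_position: int | None
    optimal_window: tuple[int, int] | None
    threshold_fraction: float


def window_profile(
    summaries: Sequence[EditingSummary],
    denominator: str = "without_indels",
    threshold_fraction: float = 0.5,
) -> WindowProfile:
    """Infer an editor's editing window from multi-site summaries.

    Site-level total conversion frequencies are collected per protospacer
    position (positions where a site lacks the source base contribute
    nothing). The inferred optimal window is the maximal contiguous run of
    positions, containing the peak, whose median frequency is at least
    ``threshold_fraction`` of the peak median (half-maximum by default).
    Peak ties break toward the lower position. Site order is irrelevant.
    """
    if not summaries:
        raise ValueError("need at least one site summary")
    per_pos: dict[int, list[float]] = {}
    for s in summaries:
        freqs = (
            s.conversion_without_indels
            if denominator == "without_indels"
            else s.conversion_with_indels
        )
        for pos in freqs:
            v = s.total_conversion(pos, denominator)
            if not math.isnan(v):
                per_pos.setdefault(pos, []).append(v)
    stats = {
        pos: {
            "median": float(np.median(vals)),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
            "n": len(vals),
        }
        for pos, vals in sorted(per_pos.items())
    }
    if not stats:
        return WindowProfile(stats, None, None, threshold_fraction)
    peak = min(stats, key=lambda p: (-stats[p]["median"], p))
    cutoff = threshold_fraction * stats[peak]["median"]
    lo = hi = peak
    while lo - 1 in stats and stats[lo - 1]["median"] >= cutoff:
        lo -= 1
    while hi + 1 in stats and stats[hi + 1]["median"] >= cutoff:
        hi += 1
    return WindowProfile(stats, peak, (lo, hi), threshold_fraction)


def motif_preference(summaries: Sequence[EditingSummary]) -> dict[str, dict[str, float]]:
    """5'-context preference of editing across sites.

    Each site contributes its maximal conversion frequency (at the peak
    position), grouped by the reference base immediately 5' of the edited
    base (AN/CN/GN/TN motifs, N = the source base). Sites whose peak base
    has no 5' neighbour (reference position 0) are excluded with a warning.
    Returns ``{motif: {mean, sd, n}}``.
    """
    import warnings

    groups: dict[str, list[float]] = {}
    for s in summaries:
        if s.peak_position is None:
            continue
        ref_i = s.protospacer_interval[0] + s.peak_position - 1
        if ref_i == 0:
            warnings.warn("site peak at reference position 0 has no 5' context; excluded")
            continue
        motif = s.reference[ref_i - 1] + s.source_base
        groups.setdefault(motif, []).append(s.total_conversion(s.peak_position))
    return {
        motif: {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "n": len(vals),
        }
        for motif, vals in sorted(groups.items())
    }
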