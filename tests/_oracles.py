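"""Independent brute-force oracles used to check the designers.

Everything here is written with plain nested loops and local helpers so it
shares no code path with the package implementation (editor window/chemistry
data is shared, since that is input data, not algorithm).
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}

_CODON_TABLE = {}


def _build_codon_table():
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    i = 0
    for a in bases:
        for b in bases:
            for c in bases:
                _CODON_TABLE[a + b + c] = aas[i]
                i += 1


_build_codon_table()


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def pam_ok(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in _IUPAC[p] for b, p in zip(seq, pattern)
    )


def brute_scan(sequence: str, pam: str):
    """All PAM-valid 23-nt frames, as {(protospacer, pam, (start,end), strand)}."""
    sequence = sequence.upper()
    hits = set()
    for i in range(len(sequence) - 22):
        frame = sequence[i : i + 23]
        if "N" in frame:
            continue
        if pam_ok(frame[20:], pam):
            hits.add((frame[:20], frame[20:], (i, i + 23), "+"))
        r = rc(frame)
        if pam_ok(r[20:], pam):
            hits.add((r[:20], r[20:], (i, i + 23), "-"))
    return hits


def _window(editor, mode):
    w = editor.window
    return (w.optimal_start, w.optimal_end) if mode == "optimal" else (w.editable_start, w.editable_end)


def _frame_pos(i, strand, p):
    """1-based protospacer position of locus position p in frame starting at i."""
    pos = p - i + 1 if strand == "+" else (i + 22) - p + 1
    return pos if 1 <= pos <= 20 else None


def brute_splice_guides(sequence, exons, editor, mode, pam):
    """Splice-disruption guide keys for a +-strand gene, by exhaustive scan.

    Returns {(protospacer, interval, strand, proto_pos, locus_pos, kind)}.
    """
    sequence = sequence.upper()
    sites = []
    for j in range(len(exons) - 1):
        e = exons[j][1]
        if sequence[e : e + 2] == "GT":
            sites.append(("donor", (e, e + 1)))
        s = exons[j + 1][0]
        if sequence[s - 2 : s] == "AG":
            sites.append(("acceptor", (s - 2, s - 1)))
    lo, hi = _window(editor, mode)
    src = editor.conversion.source_base
    hits = set()
    for proto, pamseq, (i, j), strand in brute_scan(sequence, pam):
        for kind, positions in sites:
            for p in positions:
                if not i <= p < j:
                    continue
                pos = _frame_pos(i, strand, p)
                if pos is None or not lo <= pos <= hi:
                    continue
                base = sequence[p] if strand == "+" else _COMP[sequence[p]]
                if base == src:
                    hits.add((proto, (i, j), strand, pos, p, kind))
    return hits


def brute_codon_outcomes(codon, editor, include_minor=False):
    conv = editor.conversion
    products = conv.product_bases if include_minor else tuple(
        b for b in conv.product_bases if b not in conv.minor
    )
    out = set()
    for strand in "+-":
        for i in range(3):
            base = codon[i] if strand == "+" else _COMP[codon[i]]
            if base != conv.source_base:
                continue
            for prod in products:
                new = prod if strand == "+" else _COMP[prod]
                edited = codon[:i] + new + codon[i + 1 :]
                out.add((edited, _CODON_TABLE[edited], strand))
    return out


def brute_ptc_intro_guides(sequence, exons, cds, editor, mode, pam):
    """PTC-introduction guide keys for a +-strand gene.

    Returns {(protospacer, interval, strand, proto_pos, locus_pos)}.
    """
    sequence = sequence.upper()
    cds_pos = [p for s, e in cds for p in range(s, e)]
    cds_seq = "".join(sequence[p] for p in cds_pos)
    lo, hi = _window(editor, mode)
    conv = editor.conversion
    products = tuple(b for b in conv.product_bases if b not in conv.minor)
    frames = brute_scan(sequence, pam)
    hits = set()
    n_codons = len(cds_seq) // 3
    for k in range(1, n_codons - 1):
        codon = cds_seq[3 * k : 3 * k + 3]
        if _CODON_TABLE[codon] == "*":
            continue
        for strand in "+-":
            for i in range(3):
                base = codon[i] if strand == "+" else _COMP[codon[i]]
                if base != conv.source_base:
                    continue
                makes_stop = any(
                    _CODON_TABLE[
                        codon[:i] + (p if strand == "+" else _COMP[p]) + codon[i + 1 :]
                    ]
                    == "*"
                    for p in products
                )
                if not makes_stop:
                    continue
                locus_p = cds_pos[3 * k + i]
                for proto, pamseq, (fi, fj), fstrand in frames:
                    if fstrand != strand or not fi <= locus_p < fj:
                        continue
                    pos = _frame_pos(fi, fstrand, locus_p)
                    if pos is not None and lo <= pos <= hi:
                        hits.add((proto, (fi, fj), fstrand, pos, locus_p))
    return hits


def brute_offtargets(genome, protospacer, pam, max_mm):
    hits = set()
    for proto, pamseq, iv, strand in brute_scan(genome, pam):
        mm = sum(a != b for a, b in zip(proto, protospacer))
        if mm <= max_mm:
            hits.add((iv, strand, mm))
    return hits


def brute_venn_regions(sets: dict):
    """Membership pattern -> count by direct set algebra."""
    union = set()
    for s in sets.values():
        union |= set(s)
    regions = {}
    for item in union:
        pattern = frozenset(n for n, s in sets.items() if item in s)
        regions[pattern] = regions.get(pattern, 0) + 1
    return regions
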