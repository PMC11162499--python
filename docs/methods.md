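# Methods

## Scope and model

`gbekit` implements the computational side of characterising and deploying
glycosylase-based (deaminase-free) base editors — editors that excise the
target base (T or C) with an engineered uracil DNA glycosylase fused to
Cas9 nickase, leaving an abasic site whose repair yields predominantly
transversion products (T→C/G, "T-to-S"; C→G with secondary C→T). Three
things are modelled:

1. **Editors as data.** An editor is a chemistry (source base, ordered
   product bases, predominant/minor flags), an editing window over 1-based
   protospacer positions 1–20 (PAM at 21–23), and a PAM pattern. Windows
   distinguish *editable* (any detectable activity) from *optimal* (the
   high-efficiency sub-range), optionally with a single *peak* position.
   Editors for which only one published range exists store it as both
   optimal and editable. Canonical ABE/CBE (optimal 4–8, editable 3–9) and
   the gGBE window (optimal 4–8) are community-convention defaults rather
   than measured values in this code base; both are overridable through the
   JSON editor config, which round-trips the registry bit-identically.
   Minor products (e.g. trace T→A) are recorded in the chemistry but
   excluded from design-time intended edits.

2. **Guide design as window-constrained enumeration.** Every 23-nt frame on
   either strand whose positions 21–23 match the PAM (IUPAC-aware; frames
   containing N excluded) is a protospacer placement. A placement becomes a
   candidate for an application when a targetable base — a splice-signal
   dinucleotide base (intron-initial GT donor / intron-terminal AG
   acceptor), a codon base whose edit creates a premature stop, or a
   premature stop whose edit restores a sense codon — read *on the
   protospacer strand* equals the editor's source base and falls inside the
   requested window. Edits on the antisense strand complement back into the
   sense codon; the initiator codon and the natural stop are never PTC
   targets. Minus-strand gene models are designed in their coding view
   (reverse-complemented, intervals mirrored) and the results mirrored
   back, which makes designs exactly strand-symmetric by construction.
   Candidate identity for cross-editor (Venn) comparison is
   (protospacer sequence, locus interval, guide strand); an sgRNA belongs
   to an editor's set if it is valid for at least one targetable base.

3. **Outcome quantification as per-column counting over global
   alignments.** Reads are globally aligned to the amplicon reference with
   affine gap scores (match +2, mismatch −2, open −10, extend −1 by
   default — chosen so single-event reads align unambiguously) and tallied
   per reference position into A/C/G/T/deletion counts; insertions are
   keyed by reference gap position. A read is an *indel read* iff any gap
   event overlaps the quantification window (protospacer ± 3 bp flank by
   default). Reads shorter than that window are discarded and counted.
   Base qualities are ignored; no sequencing-error floor is subtracted.

## Statistics

With counts `c(T→X)` at a reference T position:

* **purity** (e.g. T-to-G) = `c(T→G) / [c(T→A) + c(T→C) + c(T→G)]`
* **T-to-S ratio** = `[c(T→C) + c(T→G)] / [c(T→A) + c(T→C) + c(T→G)]`

Both are reported as absent when the denominator is zero, and the ratio's
numerator is a superset of the purity's, so ratio ≥ purity wherever both
are defined. Two denominator conventions are always computed, because the
external tools this replaces do not pin one: *without_indels* restricts
counts to reads without an indel in the quantification window;
*with_indels* uses all reads and additionally adds deletion calls at the
position to the denominator, so indel outcomes depress the ratio — the
direction seen when both variants of the ratio are reported side by side.
Indel frequency is simply indel reads / total reads.

**Window inference.** Site-level total conversion frequencies are pooled
per protospacer position (median and quartiles across sites); the peak is
the position with the highest median, ties breaking toward the PAM-distal
(lower) position, and the inferred optimal window is the maximal
contiguous run containing the peak whose median is at least half the peak
median (a full-width-at-half-maximum convention; the fraction is a
parameter). **Motif preference** groups each site's maximal conversion
frequency by the reference base 5' of the edited base; sites whose target
sits at reference position 0 are excluded with a warning. **Fold changes**
between two efficiencies are reported to 2 significant figures.

## Synthetic data

The read generator draws, per read, either one indel (probability
`indel_probability`; signed length uniform over a configurable set; start
uniform in the quantification window) or per-position substitutions from
the configured probabilities, then overlays a uniform per-base miscall
error. Indels and programmed substitutions are mutually exclusive within a
read because the downstream statistics treat conversion and indel outcomes
as disjoint classes. Defaults used in the shipped round-trip analyses —
T5→G 0.40, T5→C 0.20, indel 0.15, n = 10,000 reads on a 60-bp amplicon,
and 20 sites with window weights 0.5 over positions 3–7 (0.6 at position
5) against 0.1 over the rest of positions 2–11 — are chosen to emulate the
efficiency, byproduct and window scales typical of engineered
glycosylase-based T editors.

The gene generator builds multi-exon loci with canonical GT/AG introns and
an in-frame CDS (ATG, random sense codons, terminal TAA), optionally
planting a premature stop mid-CDS and/or an AGG PAM in the intron interior
so a chosen splice-site base lands at a chosen protospacer position; every
planted feature is recorded in a ground-truth ledger. A `pam_free` mode
generates backgrounds with no GG/CC dinucleotide (hence no NGG PAM on
either strand) for negative-control designs; in that mode no CDS is
annotated, since the background is not constrained to sense codons.

What the generator does **not** emulate: PCR amplification bias, paired
ends, quality-score structure, position-dependent error, repair-pathway
kinetics, isoform complexity, chromatin context. Passing round-trip tests
therefore demonstrates internal consistency of designer/quantifier logic
at realistic parameter scales, not performance on real sequencing data.

## Numerical and design choices

* Alignment tie-breaking uses the aligner's deterministic first optimal
  alignment; equal-length reads take a gap-free fast path (an equal-length
  read with compensating insertion + deletion would be miscounted as
  substitutions, a case the generator never produces and real amplicon
  data makes vanishingly rare at these read lengths).
* Coordinates are 0-based half-open internally; GFF3 I/O converts from
  1-based inclusive; protospacer positions are 1-based with PAM at 21–23.
* Scanning-mutagenesis planning: the alanine scan substitutes native
  alanines with valine (A>V) so every residue in a segment is covered;
  the R/D/V scans have no published fallback, so a native residue equal to
  the scheme target is skipped rather than no-op'd. Region partitioning
  into 8-residue segments is left-aligned from the region start.
* The UNG1↔UNG2 residue map is a constant offset (+9, the nuclear
  isoform's N-terminal extension); mapping UNG2 residues 1–9 back to UNG1
  is a range error.
* Any edit of either splice-dinucleotide base counts as disruption; no
  attempt is made to score splicing-outcome strength or sgRNA efficacy.
* All randomness flows from a single top-level seed fanned out per stage;
  identical config + seed reproduces every artifact byte-for-byte.

## Problem sizes in shipped analyses

The round-trip analyses and `scripts/acceptance.py` use 10,000 reads per
amplicon (binomial SE ≈ 0.005 at p = 0.4), 20 replicate seeds or 20 sites
for window inference, 50 random 300-nt loci for designer/oracle
equivalence, and a 16-gene synthetic panel for cross-editor
classification. These sizes put sampling error well below the effect
sizes being checked while keeping a full run in the tens of seconds.

## Known limitations

* Published counts of genome-wide sgRNA candidates for specific human gene
  panels depend on the annotation build and isoform choices of the
  original analyses and are not recomputed here; the same enumeration can
  be run on user-supplied FASTA/GFF3 via the CLI.
* The off-target scan is an exhaustive Hamming scan suitable for loci and
  small genomes, not an indexed genome-scale search, and allows no bulges.
* The quantifier trusts its own global alignment; it does not implement
  allele plots, UMI handling, or quality-aware calling.
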