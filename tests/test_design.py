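"""Guide designers against exhaustive brute-force oracles and worked examples."""

import numpy as np
import pytest

import _oracles as oracle
from conftest import random_dna
from gbekit.design import (
    classify_across_editors,
    codon_edit_outcomes,
    find_offtargets,
    find_ptc_bypass_guides,
    find_ptc_introduction_guides,
    find_splice_site_guides,
    predict_reporter_restoration,
    scan_protospacers,
    GuideCandidate,
)
from gbekit.editors import can_edit
from gbekit.genes import GeneModel
from gbekit.simulate import PlantedGuide, SimConfig, simulate_gene_model


# ---------------------------------------------------------------------------
# protospacer scanning
# ---------------------------------------------------------------------------

def test_scan_single_frame_plus_strand_only():
    seq = "T" * 20 + "AGG"  # one frame; reverse complement PAM is CCT -> no - hit
    frames = scan_protospacers(seq, "NGG")
    assert len(frames) == 1
    f = frames[0]
    assert (f.protospacer, f.pam, f.interval, f.strand) == ("T" * 20, "AGG", (0, 23), "+")


def test_scan_polyA_has_no_ngg_pam():
    assert scan_protospacers("A" * 30, "NGG") == []


def test_scan_frames_with_N_excluded():
    seq = "T" * 10 + "N" + "T" * 9 + "AGG"
    assert scan_protospacers(seq, "NGG") == []


def test_scan_rejects_malformed_pam():
    with pytest.raises(ValueError):
        scan_protospacers("A" * 30, "NQG")


def test_scan_matches_bruteforce_on_random_sequences(rng):
    for pam in ("NGG", "NGN"):
        for _ in range(5):
            seq = random_dna(rng, 200)
            got = {(f.protospacer, f.pam, f.interval, f.strand) for f in scan_protospacers(seq, pam)}
            assert got == oracle.brute_scan(seq, pam)


def test_scan_output_ordered_by_coordinate():
    seq = "CC" + "T" * 19 + "AGGA"
    frames = scan_protospacers(seq, "NGN")
    assert [f.interval[0] for f in frames] == sorted(f.interval[0] for f in frames)


# ---------------------------------------------------------------------------
# splice-site guides
# ---------------------------------------------------------------------------

def test_planted_donor_T_at_position5_yields_gtbe_candidate(registry):
    gene, ledger = simulate_gene_model(
        SimConfig(planted_guides=(PlantedGuide(kind="donor", protospacer_position=5),)),
        seed=3,
    )
    cands = find_splice_site_guides(gene, registry["gTBEv3"])
    planted = ledger["planted_guides"][0]
    hit = [
        c
        for c in cands
        if c.targeted_locus_position == planted["targeted_position"]
        and c.targeted_base_position == 5
    ]
    assert hit and hit[0].application == "SD_disruption"
    assert hit[0].source_base == "T"
    assert set(hit[0].intended_products) == {"C", "G"}


def test_pam_free_background_yields_no_candidates(registry):
    gene, _ = simulate_gene_model(SimConfig(pam_free=True), seed=4)
    for name in ("gTBEv3", "ABE", "CBE", "gGBE"):
        assert find_splice_site_guides(gene, registry[name]) == []


def test_abe_cannot_use_donor_when_antisense_A_out_of_window(registry):
    # Donor GT at locus 26-27; the only + frame (AGG PAM at 41-43) puts the
    # donor T at protospacer position 7 (inside gTBEv3's optimal window). The
    # dinucleotide read on the - strand is AC, so ABE could in principle
    # target the A — but exon1 contains no C, so no - strand frame has a
    # valid PAM, and ABE (A->G) gets no candidate.
    exon1 = "ATGAAATTTAAATTTAAATTTAAATT"  # 26 nt, C-free
    intron = "GT" + "A" * 13 + "AGG" + "A" * 6 + "AG"  # 26 nt, PAM at 41-43
    exon2 = "CCCTTTGGGTAA"
    seq = exon1 + intron + exon2
    gene = GeneModel("fx", seq, "+", ((0, 26), (52, 64)))
    gtbe_cands = find_splice_site_guides(gene, registry["gTBEv3"])
    assert any(c.targeted_base_position == 7 for c in gtbe_cands)
    assert find_splice_site_guides(gene, registry["ABE"]) == []


def test_splice_guides_match_bruteforce_on_random_loci(rng, registry):
    editors = [registry[n] for n in ("gTBEv3", "gCBEv2", "ABE", "gGBE")]
    for _ in range(10):
        gene, _ = simulate_gene_model(SimConfig(), seed=int(rng.integers(2**31)))
        for editor in editors:
            for mode in ("optimal", "editable"):
                got = {
                    (c.protospacer, c.interval, c.guide_strand,
                     c.targeted_base_position, c.targeted_locus_position,
                     "donor" if c.application == "SD_disruption" else "acceptor")
                    for c in find_splice_site_guides(gene, editor, mode=mode)
                }
                expected = oracle.brute_splice_guides(
                    gene.sequence, gene.exons, editor, mode, editor.pam
                )
                assert got == expected


def test_reverse_complement_symmetry(registry):
    plus, _ = simulate_gene_model(SimConfig(planted_guides=(PlantedGuide(),)), seed=21)
    L = len(plus.sequence)
    from gbekit._seq import revcomp
    from gbekit.genes import mirror_interval

    minus = GeneModel(
        plus.id,
        revcomp(plus.sequence),
        "-",
        tuple(sorted(mirror_interval(e, L) for e in plus.exons)),
        tuple(sorted(mirror_interval(c, L) for c in plus.cds)),
    )
    for editor in (registry["gTBEv3"], registry["gCBEv2"]):
        c_plus = find_splice_site_guides(plus, editor)
        c_minus = find_splice_site_guides(minus, editor)
        mirrored = {
            (c.protospacer, mirror_interval(c.interval, L),
             "+" if c.guide_strand == "-" else "-", c.targeted_base_position)
            for c in c_minus
        }
        assert mirrored == {
            (c.protospacer, c.interval, c.guide_strand, c.targeted_base_position)
            for c in c_plus
        }


def test_widening_window_never_removes_candidates(registry):
    gene, _ = simulate_gene_model(SimConfig(planted_guides=(PlantedGuide(),)), seed=17)
    for editor in (registry["gTBEv3"], registry["gCBEv2"], registry["CGBE1"]):
        opt = {c.key + (c.targeted_base_position,) for c in find_splice_site_guides(gene, editor, mode="optimal")}
        edi = {c.key + (c.targeted_base_position,) for c in find_splice_site_guides(gene, editor, mode="editable")}
        assert opt <= edi


def test_every_candidate_satisfies_window_and_pam_posthoc(registry):
    from gbekit._seq import matches_iupac

    gene, _ = simulate_gene_model(SimConfig(planted_guides=(PlantedGuide(),)), seed=23)
    for editor in (registry["gTBEv3"], registry["ABE"]):
        for mode in ("optimal", "editable"):
            for c in find_splice_site_guides(gene, editor, mode=mode):
                assert can_edit(editor, c.source_base, c.targeted_base_position, mode)
                assert matches_iupac(c.pam, editor.pam)


# ---------------------------------------------------------------------------
# codon edit outcomes
# ---------------------------------------------------------------------------

def test_codon_outcomes_agree_with_bruteforce_for_all_codons(registry):
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    for editor in registry.values():
        for codon in codons:
            assert codon_edit_outcomes(codon, editor) == oracle.brute_codon_outcomes(codon, editor)
            assert codon_edit_outcomes(codon, editor, include_minor=True) == (
                oracle.brute_codon_outcomes(codon, editor, include_minor=True)
            )


def test_tag_with_gtbe_reaches_gln_and_glu(registry):
    outcomes = codon_edit_outcomes("TAG", registry["gTBEv3"])
    edited = {c for c, aa, strand in outcomes if strand == "+"}
    assert {"CAG", "GAG"} <= edited


@pytest.mark.parametrize("codon,stops", [("TAC", {"TAA", "TAG"}), ("TCA", {"TGA", "TAA"})])
def test_ggbe_stop_producing_codons(registry, codon, stops):
    outcomes = codon_edit_outcomes(codon, registry["gGBE"])
    assert {c for c, aa, _ in outcomes if aa == "*"} == stops


def test_invalid_codon_rejected(registry):
    with pytest.raises(ValueError):
        codon_edit_outcomes("TAXG", registry["ABE"])
    with pytest.raises(ValueError):
        codon_edit_outcomes("TAX", registry["ABE"])


# ---------------------------------------------------------------------------
# PTC introduction / bypass
# ---------------------------------------------------------------------------

def test_ptc_introduction_matches_bruteforce(rng, registry):
    editors = [registry[n] for n in ("CBE", "gGBE", "gCBEv2", "gTBEv3")]
    for _ in range(6):
        gene, _ = simulate_gene_model(SimConfig(), seed=int(rng.integers(2**31)))
        for editor in editors:
            got = {
                (c.protospacer, c.interval, c.guide_strand,
                 c.targeted_base_position, c.targeted_locus_position)
                for c in find_ptc_introduction_guides(gene, editor, mode="editable")
            }
            expected = oracle.brute_ptc_intro_guides(
                gene.sequence, gene.exons, gene.cds, editor, "editable", editor.pam
            )
            assert got == expected


def test_ptc_introduction_requires_cds(registry):
    gene = GeneModel("nocds", "A" * 30 + "GTAAGT" + "A" * 30, "+", ((0, 30), (36, 66)))
    with pytest.raises(ValueError):
        find_ptc_introduction_guides(gene, registry["CBE"])


def test_ptc_introduction_stop_outcomes_only(registry):
    gene, _ = simulate_gene_model(SimConfig(), seed=29)
    for c in find_ptc_introduction_guides(gene, registry["gGBE"], mode="editable"):
        assert c.outcomes and all(aa == "*" for _, aa in c.outcomes)


def test_ptc_bypass_on_planted_tag(registry):
    gene, ledger = simulate_gene_model(
        SimConfig(planted_ptc="TAG", planted_guides=()), seed=31
    )
    k = ledger["ptc_codon_index"]
    cands = find_ptc_bypass_guides(gene, k, registry["gTBEv3"], mode="editable")
    for c in cands:
        assert c.application == "PTC_bypass"
        assert all(aa != "*" for _, aa in c.outcomes)
    # chemistry on sense position 1 of TAG reaches CAG (Gln) / GAG (Glu)
    sense = [c for c in cands if c.guide_strand == "+" and {o[0] for o in c.outcomes} & {"CAG", "GAG"}]
    antisense_ok = not any(
        aa == "*" for c in cands for _, aa in c.outcomes
    )
    assert antisense_ok
    assert sense or cands == []  # sense frames exist only if a PAM landed there


def test_ptc_bypass_rejects_non_stop_codon(registry):
    gene, _ = simulate_gene_model(SimConfig(), seed=37)
    with pytest.raises(ValueError):
        find_ptc_bypass_guides(gene, 1, registry["gTBEv3"])  # codon 1 is sense


# ---------------------------------------------------------------------------
# reporter restoration
# ---------------------------------------------------------------------------

def _reporter_fixture(mutated_base):
    # acceptor A at index 24, mutated second base at index 25 (protospacer
    # position 6 of the + frame starting at 20)
    seq = "C" * 20 + "TTTTA" + mutated_base + "TTTTTTTTTTTTTT" + "AGG" + "C" * 5
    guide = GuideCandidate(
        protospacer=seq[20:40],
        pam=seq[40:43],
        interval=(20, 43),
        guide_strand="+",
        targeted_base_position=6,
        targeted_locus_position=25,
        source_base=mutated_base,
        intended_products=(),
        application="reporter_restoration",
    )
    return seq, guide


def test_at_acceptor_restored_by_t_to_g_chemistry(registry):
    seq, guide = _reporter_fixture("T")
    assert predict_reporter_restoration(seq, 25, registry["gTBEv3"], guide)


def test_ac_acceptor_restored_by_c_to_g_chemistry(registry):
    seq, guide = _reporter_fixture("C")
    assert predict_reporter_restoration(seq, 25, registry["gCBEv2"], guide)


def test_orthogonality_wrong_chemistry_cannot_restore(registry):
    seq, guide = _reporter_fixture("T")
    assert not predict_reporter_restoration(seq, 25, registry["gCBEv2"], guide)
    seq, guide = _reporter_fixture("C")
    assert not predict_reporter_restoration(seq, 25, registry["gTBEv3"], guide)


def test_restoration_errors_when_guide_misses_mutation(registry):
    seq, guide = _reporter_fixture("T")
    with pytest.raises(ValueError):
        predict_reporter_restoration(seq, 5, registry["gTBEv3"], guide)


# ---------------------------------------------------------------------------
# venn classification
# ---------------------------------------------------------------------------

def _fake_candidates(keys):
    out = []
    for proto, start in keys:
        out.append(
            GuideCandidate(
                protospacer=proto,
                pam="AGG",
                interval=(start, start + 23),
                guide_strand="+",
                targeted_base_position=5,
                targeted_locus_position=start + 4,
                source_base="T",
                intended_products=("G",),
                application="SD_disruption",
            )
        )
    return out


def test_identical_sets_fully_overlap():
    keys = [("A" * 20, i) for i in range(5)]
    venn = classify_across_editors({"e1": _fake_candidates(keys), "e2": _fake_candidates(keys)})
    assert venn.union_size == 5
    assert venn.overlap("e1", "e2") == 5
    assert venn.exclusive("e1") == venn.exclusive("e2") == 0


def test_disjoint_sets_have_no_intersection():
    a = _fake_candidates([("A" * 20, i) for i in range(3)])
    b = _fake_candidates([("C" * 20, i + 100) for i in range(4)])
    venn = classify_across_editors({"a": a, "b": b})
    assert venn.union_size == 7
    assert venn.overlap("a", "b") == 0
    assert venn.exclusive("a") == 3 and venn.exclusive("b") == 4


def test_venn_regions_match_set_algebra(rng):
    names = ["e1", "e2", "e3", "e4"]
    pool = [("T" * 19 + "ACGT"[i % 4], int(i)) for i in range(40)]
    sets = {}
    for n in names:
        chosen = [pool[i] for i in rng.choice(len(pool), size=15, replace=False)]
        sets[n] = _fake_candidates(chosen)
    venn = classify_across_editors(sets)
    expected = oracle.brute_venn_regions(
        {n: {c.key for c in cands} for n, cands in sets.items()}
    )
    assert dict(venn.region_counts) == expected
    assert venn.union_size == sum(expected.values())
    assert all(v >= 0 for v in venn.region_counts.values())


# ---------------------------------------------------------------------------
# off-target scan
# ---------------------------------------------------------------------------

def test_exact_site_found_with_zero_mismatches(rng):
    proto = random_dna(rng, 20)
    genome = random_dna(rng, 200) + proto + "TGG" + random_dna(rng, 200)
    hits = find_offtargets(genome, proto, "NGG", 0)
    assert ((200, 223), "+", 0) in hits


def test_no_hits_when_site_absent():
    genome = "AT" * 100  # no NGG PAM anywhere
    assert find_offtargets(genome, "ACGT" * 5, "NGG", 3) == []


def test_offtargets_match_bruteforce(rng):
    proto = random_dna(rng, 20)
    genome = random_dna(rng, 5000)
    got = set(find_offtargets(genome, proto, "NGG", 3))
    assert got == oracle.brute_offtargets(genome, proto, "NGG", 3)
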