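"""Small-RNA pipeline unit tests: trimming, alignment, classes, counts."""

import numpy as np
import pytest

from risipipe.reference_io import FeatureInterval, RrnaReference, SmallRead, revcomp
from risipipe.smallrna import (
    ADAPTOR_3P,
    OTHER_MAPPED,
    RISIRNA,
    SENSE_RRNA,
    UNMAPPED,
    CountSummary,
    ReadAligner,
    SmallAlignment,
    align_reads,
    classify_read,
    count_untemplated_3U,
    fold_enrichment,
    length_filter,
    per_region_counts,
    risirna_rpm,
    size_firstnt_profile,
    summarize_counts,
    trim_3p_adaptor,
)

from _oracles import brute_force_trim

RNG = np.random.default_rng(20200904)


def _rand(n: int) -> str:
    return "".join(np.array(list("ACGT"))[RNG.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# trimming


def test_trim_exact_adaptor_after_insert():
    insert = _rand(22)
    read = SmallRead("r", insert + ADAPTOR_3P)
    out = trim_3p_adaptor(read)
    assert out is not None and out.seq == insert


def test_trim_rejects_read_without_adaptor():
    assert trim_3p_adaptor(SmallRead("r", _rand(40))) is None


def test_trim_one_mismatch_matches_brute_force():
    insert = _rand(22)
    mutated = "A" + ADAPTOR_3P[1:] if ADAPTOR_3P[0] != "A" else "C" + ADAPTOR_3P[1:]
    read = SmallRead("r", insert + mutated)
    out = trim_3p_adaptor(read, max_mismatch=1)
    expected = brute_force_trim(read.seq, ADAPTOR_3P, 5, 1)
    assert expected == len(insert)
    assert out is not None and len(out.seq) == expected


def test_trim_partial_adaptor_prefix_at_read_end():
    insert = _rand(22)
    read = SmallRead("r", insert + ADAPTOR_3P[:8])  # only 8 nt of adaptor sequenced
    out = trim_3p_adaptor(read, min_overlap=5, max_mismatch=0)
    assert out is not None and out.seq == insert


def test_trim_agrees_with_brute_force_on_random_reads():
    for _ in range(300):
        seq = _rand(int(RNG.integers(10, 60)))
        for mm in (0, 1, 2):
            expected = brute_force_trim(seq, ADAPTOR_3P, 5, mm)
            got = trim_3p_adaptor(SmallRead("r", seq), max_mismatch=mm)
            if expected is None:
                assert got is None
            else:
                assert got is not None and len(got.seq) == expected


@pytest.mark.parametrize(
    "length, kept", [(0, False), (17, False), (18, True), (22, True), (30, True), (31, False)]
)
def test_length_filter_boundaries(length, kept):
    assert length_filter(SmallRead("r", "A" * length)) is kept


# ---------------------------------------------------------------------------
# alignment


def test_align_sense_substring(toy_ref):
    seq = toy_ref.seq("pre-rRNA")[500:522]
    (alns,) = align_reads([SmallRead("r", seq)], toy_ref)
    assert any(
        a.transcript_id == "pre-rRNA" and a.strand == "sense" and a.start == 500
        and a.end == 522 and a.mismatches == 0 and a.soft_tail == ""
        for a in alns
    )


def test_align_antisense_substring(toy_ref):
    seq = revcomp(toy_ref.seq("pre-rRNA")[700:722])
    (alns,) = align_reads([SmallRead("r", seq)], toy_ref)
    hits = [a for a in alns if a.strand == "antisense"]
    assert hits and hits[0].start == 700 and hits[0].end == 722


def test_align_reports_every_occurrence():
    motif = _rand(22)
    seq = _rand(100) + motif + _rand(100) + motif + _rand(50)
    ref = RrnaReference(transcripts={"t": seq}, features=[])
    (alns,) = align_reads([SmallRead("r", motif)], ref)
    sense_hits = [a for a in alns if a.strand == "sense"]
    assert len(sense_hits) == 2
    assert {a.start for a in sense_hits} == {100, 222}


def test_align_soft_tail_is_minimal(toy_ref):
    core = revcomp(toy_ref.seq("pre-rRNA")[800:822])
    # tail chosen to mismatch the template continuation immediately
    unit = toy_ref.seq("pre-rRNA")
    next_tmpl = revcomp(unit[799])  # template continuation base
    tail_base = "A" if next_tmpl != "A" else "C"
    (alns,) = align_reads([SmallRead("r", core + tail_base * 2)], toy_ref)
    anti = [a for a in alns if a.strand == "antisense" and a.start == 800]
    assert anti and anti[0].soft_tail == tail_base * 2


def test_align_empty_reference_rejected():
    with pytest.raises(ValueError):
        ReadAligner(RrnaReference(transcripts={}, features=[]))


# ---------------------------------------------------------------------------
# classification


def _aln(tid, start, end, strand, mm=0, tail=""):
    return SmallAlignment("r", tid, start, end, strand, mm, tail)


def test_classify_antisense_in_26s_is_risirna(toy_ref):
    f = toy_ref.feature("26S")
    assert classify_read([_aln("pre-rRNA", f.start + 10, f.start + 32, "antisense")], toy_ref) == RISIRNA


def test_classify_sense_in_18s_is_sense_rrna(toy_ref):
    f = toy_ref.feature("18S")
    assert classify_read([_aln("pre-rRNA", f.start + 5, f.start + 27, "sense")], toy_ref) == SENSE_RRNA


def test_classify_decoy_hit_is_other_mapped(toy_ref):
    assert classify_read([_aln("decoy-1", 10, 32, "sense")], toy_ref) == OTHER_MAPPED


def test_classify_no_alignment_is_unmapped(toy_ref):
    assert classify_read([], toy_ref) == UNMAPPED


def test_classify_priority_risirna_over_sense(toy_ref):
    f18, f26 = toy_ref.feature("18S"), toy_ref.feature("26S")
    alns = [
        _aln("pre-rRNA", f18.start, f18.start + 22, "sense"),
        _aln("pre-rRNA", f26.start, f26.start + 22, "antisense"),
    ]
    assert classify_read(alns, toy_ref) == RISIRNA


def test_classify_sense_spacer_is_other_mapped(toy_ref):
    f = toy_ref.feature("18S")
    # 10 nt in 18S, 12 nt in ITS1: majority in the spacer
    alns = [_aln("pre-rRNA", f.end - 10, f.end + 12, "sense")]
    assert classify_read(alns, toy_ref) == OTHER_MAPPED


# ---------------------------------------------------------------------------
# counting and normalization


def _classified(toy_ref, spec):
    """spec: list of (class, alignment-or-None) -> classified triples."""
    out = []
    for i, (cls, aln) in enumerate(spec):
        read = SmallRead(f"r{i}", "A" * 22)
        out.append((read, [aln] if aln else [], cls))
    return out


def test_summarize_counts_denominator_rule(toy_ref):
    f18 = toy_ref.feature("18S")
    f26 = toy_ref.feature("26S")
    spec = (
        [(SENSE_RRNA, _aln("pre-rRNA", f18.start, f18.start + 22, "sense"))] * 4
        + [(RISIRNA, _aln("pre-rRNA", f26.start, f26.start + 22, "antisense"))] * 2
        + [(OTHER_MAPPED, _aln("decoy-1", 0, 22, "sense"))] * 4
        + [(UNMAPPED, None)] * 3
    )
    cs = summarize_counts(_classified(toy_ref, spec), toy_ref)
    assert cs.total_clean == 13
    assert cs.total_mapped == 10
    assert cs.sense_rRNA == 4
    assert cs.risiRNA == 2
    assert cs.norm_denominator == 10 - 4
    assert cs.sense_rRNA + cs.risiRNA_total + cs.other_mapped + cs.unmapped == cs.total_clean


def test_summarize_counts_all_sense_flags_zero_denominator(toy_ref):
    f18 = toy_ref.feature("18S")
    spec = [(SENSE_RRNA, _aln("pre-rRNA", f18.start, f18.start + 22, "sense"))] * 5
    cs = summarize_counts(_classified(toy_ref, spec), toy_ref)
    assert cs.norm_denominator == 0 and cs.zero_denominator
    with pytest.raises(ZeroDivisionError):
        risirna_rpm(cs)


def test_risirna_rpm_values():
    cs = CountSummary("s", risiRNA=60, norm_denominator=600_000)
    assert risirna_rpm(cs) == pytest.approx(100.0)
    cs0 = CountSummary("s", risiRNA=0, norm_denominator=600_000)
    assert risirna_rpm(cs0) == 0.0


def test_fold_enrichment_identity_and_ratio():
    a = CountSummary("a", risiRNA=100, norm_denominator=1_000_000)
    assert fold_enrichment(a, a) == pytest.approx(1.0)
    b = CountSummary("b", risiRNA=10, norm_denominator=1_000_000)
    assert fold_enrichment(a, b) == pytest.approx(10.0)


def test_fold_enrichment_zero_baseline_and_pseudocount():
    a = CountSummary("a", risiRNA=50, norm_denominator=500_000)
    b = CountSummary("b", risiRNA=0, norm_denominator=250_000)
    assert fold_enrichment(a, b) == float("inf")
    # hand computation with +1 pseudocount on both counts
    expected = ((50 + 1) * 1e6 / 500_000) / ((0 + 1) * 1e6 / 250_000)
    assert fold_enrichment(a, b, pseudocount=1) == pytest.approx(expected)


def test_normalizer_invariance_adding_sense_reads(toy_ref):
    f18 = toy_ref.feature("18S")
    f26 = toy_ref.feature("26S")
    base = (
        [(RISIRNA, _aln("pre-rRNA", f26.start, f26.start + 22, "antisense"))] * 3
        + [(OTHER_MAPPED, _aln("decoy-1", 0, 22, "sense"))] * 7
    )
    spike = [(SENSE_RRNA, _aln("pre-rRNA", f18.start, f18.start + 22, "sense"))] * 50
    rpm_a = risirna_rpm(summarize_counts(_classified(toy_ref, base), toy_ref))
    rpm_b = risirna_rpm(summarize_counts(_classified(toy_ref, base + spike), toy_ref))
    assert rpm_a == rpm_b


# ---------------------------------------------------------------------------
# per-region assignment


def test_per_region_read_inside_its1(toy_ref):
    f = toy_ref.feature("ITS1") or next(x for x in toy_ref.features if x.name == "ITS1")
    triples = _classified(
        toy_ref, [(RISIRNA, _aln("pre-rRNA", f.start + 5, f.start + 27, "antisense"))]
    )
    assert per_region_counts(triples, toy_ref) == {"ITS1": 1}


@pytest.mark.parametrize("in_first", range(1, 22))
def test_per_region_majority_and_tie_break(toy_ref, in_first):
    """22-mers crossing the 18S/ITS1 boundary at every split position.

    Majority wins; the 11/11 tie goes to the 5'-most region (18S).
    """
    boundary = toy_ref.feature("18S").end
    aln = _aln("pre-rRNA", boundary - in_first, boundary - in_first + 22, "antisense")
    counts = per_region_counts(_classified(toy_ref, [(RISIRNA, aln)]), toy_ref)
    if in_first > 11:
        assert counts == {"18S": 1}
    elif in_first < 11:
        assert counts == {"ITS1": 1}
    else:
        assert counts == {"18S": 1}  # tie: 5'-most region


# ---------------------------------------------------------------------------
# profiles


def test_size_profile_all_22g():
    reads = [SmallRead(f"r{i}", "G" + "A" * 21) for i in range(100)]
    mat = size_firstnt_profile(reads)
    assert mat.loc[22, "G"] == 100
    assert int(mat.to_numpy().sum()) == 100


def test_size_profile_empty():
    mat = size_firstnt_profile([])
    assert int(mat.to_numpy().sum()) == 0


def test_size_profile_hand_tally():
    reads = [
        SmallRead("a", "G" + "C" * 21),   # 22, G
        SmallRead("b", "G" + "C" * 21),   # 22, G
        SmallRead("c", "T" + "C" * 21),   # 22, U
        SmallRead("d", "A" + "C" * 17),   # 18, A
        SmallRead("e", "C" + "C" * 29),   # 30, C
        SmallRead("f", "G" + "C" * 30),   # 31 nt: outside range
    ]
    mat = size_firstnt_profile(reads)
    assert mat.loc[22, "G"] == 2
    assert mat.loc[22, "U"] == 1
    assert mat.loc[18, "A"] == 1
    assert mat.loc[30, "C"] == 1
    assert int(mat.to_numpy().sum()) == 5


# ---------------------------------------------------------------------------
# untemplated 3' U


def _antisense_read_with_tail(ref, pos, length, tail):
    unit = ref.seq("pre-rRNA")
    return SmallRead("r", revcomp(unit[pos : pos + length]) + tail)


def test_untemplated_u_read_matching_template_not_counted(toy_ref):
    read = _antisense_read_with_tail(toy_ref, 700, 22, "")
    (alns,) = align_reads([read], toy_ref)
    assert count_untemplated_3U(alns, toy_ref) == (0, {})


def test_untemplated_u_two_t_against_gc_template():
    # template continuation must be 'GC': bases left of pos are complement-rev
    seq = _rand(60) + "GC" + _rand(60)
    pos = 62
    ref = RrnaReference(
        transcripts={"pre-rRNA": seq},
        features=[FeatureInterval("pre-rRNA", "26S", 0, len(seq))],
    )
    # continuation = revcomp(seq[pos-2:pos]) = revcomp("GC") = "GC"
    read = SmallRead("r", revcomp(seq[pos : pos + 22]) + "TT")
    (alns,) = align_reads([read], ref)
    anti = [a for a in alns if a.strand == "antisense"]
    assert anti and anti[0].soft_tail == "TT"
    assert count_untemplated_3U(anti, ref) == (1, {2: 1})


def test_untemplated_u_absorbed_by_templated_t():
    # continuation starts with T: first tail T is templated read-through
    seq = _rand(60) + "CA" + _rand(60)
    pos = 62
    # continuation = revcomp(seq[60:62]) = revcomp("CA") = "TG"
    ref = RrnaReference(
        transcripts={"pre-rRNA": seq},
        features=[FeatureInterval("pre-rRNA", "26S", 0, len(seq))],
    )
    read = SmallRead("r", revcomp(seq[pos : pos + 22]) + "TT")
    (alns,) = align_reads([read], ref)
    anti = [a for a in alns if a.strand == "antisense"]
    # greedy alignment absorbs the first T (templated); one T remains
    assert anti and anti[0].soft_tail == "T"
    assert count_untemplated_3U(anti, ref) == (1, {1: 1})


def test_untemplated_u_fully_templated_not_counted():
    seq = _rand(60) + "AA" + _rand(60)  # continuation = "TT"
    pos = 62
    ref = RrnaReference(
        transcripts={"pre-rRNA": seq},
        features=[FeatureInterval("pre-rRNA", "26S", 0, len(seq))],
    )
    read = SmallRead("r", revcomp(seq[pos : pos + 22]) + "TT")
    (alns,) = align_reads([read], ref)
    anti = [a for a in alns if a.strand == "antisense"]
    assert anti and anti[0].soft_tail == ""
    assert count_untemplated_3U(anti, ref) == (0, {})
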