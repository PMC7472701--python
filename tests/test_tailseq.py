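"""Tail-seq unit tests: linker demultiplexing, tail calls, aggregation."""

import numpy as np
import pytest

from risipipe.reference_io import SmallRead, revcomp
from risipipe.stats import ttest_two_tailed
from risipipe.tailseq import (
    DEFAULT_LINKERS,
    FORWARD_PRIMERS,
    LinkerSet,
    TailCall,
    call_tail,
    check_forward_primer,
    classify_tail,
    compare_conditions,
    find_linker,
    run_tailseq,
    summarize_tails,
)

RNG = np.random.default_rng(42)


def _rand(n: int) -> str:
    return "".join(np.array(list("ACGT"))[RNG.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# linker set and demultiplexing


def test_linker_set_has_common_core():
    ls = LinkerSet()
    assert len(ls.core) >= 10
    assert all(seq.endswith(ls.core) for seq in ls.linkers.values())


def test_linker_set_rejects_duplicates():
    with pytest.raises(ValueError, match="distinct"):
        LinkerSet(linkers={"a": DEFAULT_LINKERS["linker-1"], "b": DEFAULT_LINKERS["linker-1"]})


def test_find_linker_exact():
    insert = _rand(50)
    read = SmallRead("r", insert + DEFAULT_LINKERS["linker-1"])
    assert find_linker(read) == (insert, "linker-1")


def test_find_linker_absent():
    assert find_linker(SmallRead("r", _rand(80))) is None


def test_find_linker_one_mismatch_identifies_linker2():
    insert = _rand(50)
    linker = DEFAULT_LINKERS["linker-2"]
    mutated = linker[:20] + ("A" if linker[20] != "A" else "C") + linker[21:]
    got = find_linker(SmallRead("r", insert + mutated), max_mismatch=1)
    assert got == (insert, "linker-2")


def test_find_linker_partial_prefix_at_read_end():
    insert = _rand(50)
    read = SmallRead("r", insert + DEFAULT_LINKERS["linker-3"][:15])
    assert find_linker(read) == (insert, "linker-3")


def test_demultiplex_partition():
    """Every read is either assigned to exactly one linker or unassigned."""
    inserts = [_rand(50) for _ in range(20)]
    reads = [
        SmallRead(f"a{i}", ins + DEFAULT_LINKERS["linker-1"]) for i, ins in enumerate(inserts[:10])
    ] + [SmallRead(f"u{i}", ins + _rand(42)) for i, ins in enumerate(inserts[10:])]
    assigned = [find_linker(r) for r in reads]
    n_assigned = sum(1 for a in assigned if a is not None)
    assert n_assigned + sum(1 for a in assigned if a is None) == len(reads)
    assert all(a[1] == "linker-1" for a in assigned[:10] if a)


# ---------------------------------------------------------------------------
# forward primer check


def test_primer_verifies_26s():
    insert = FORWARD_PRIMERS["26S"] + _rand(40)
    assert check_forward_primer(insert) == (insert, "26S")


def test_primer_verifies_58s():
    insert = FORWARD_PRIMERS["5.8S"] + _rand(40)
    assert check_forward_primer(insert) == (insert, "5.8S")


def test_primer_neither_rejected():
    assert check_forward_primer(_rand(60)) is None


def test_primer_ambiguous_rejected():
    # custom primer pair differing at one position: a read matching both
    # within one mismatch is ambiguous and must be rejected
    p1 = "CAGATCACTCTGGTTCAATGTC"
    p2 = "CAGATCACTCTGGTTCAATGTA"
    ls = LinkerSet(forward_primers={"26S": p1, "5.8S": p2})
    assert check_forward_primer(p1 + _rand(30), ls) is None
    # fixing the gene resolves it
    assert check_forward_primer(p1 + _rand(30), ls, rRNA_id="26S") is not None


# ---------------------------------------------------------------------------
# tail calling (controlled references from conftest)


def _frag(ref, trim=0):
    feat = ref.feature("26S")
    T = ref.seq("pre-rRNA")
    p0 = T.find(FORWARD_PRIMERS["26S"])
    return T[p0 : feat.end + trim]


def test_call_tail_exact_end(tail_ref_gc):
    call = call_tail(_frag(tail_ref_gc), tail_ref_gc, "26S")
    assert call is not None
    assert (call.end_offset, call.templated_ext, call.tail_class) == (0, 0, "no_tail")
    assert not call.ambiguous_boundary


def test_call_tail_oligou4_against_gc_context(tail_ref_gc):
    call = call_tail(_frag(tail_ref_gc) + "TTTT", tail_ref_gc, "26S")
    assert call is not None
    assert call.tail == "TTTT" and call.tail_class == "oligoU"
    assert call.end_offset == 0 and call.templated_ext == 0


def test_call_tail_templated_t_absorbed_and_flagged(tail_ref_t):
    # downstream context starts with T: a single trailing T is templated
    call = call_tail(_frag(tail_ref_t) + "T", tail_ref_t, "26S")
    assert call is not None
    assert call.tail_class == "no_tail"
    assert call.templated_ext == 1 and call.end_offset == 0
    assert call.ambiguous_boundary


def test_call_tail_oligou_shortened_by_templated_t(tail_ref_t):
    # drawn TTT against context "TC...": one T absorbed, two untemplated left
    call = call_tail(_frag(tail_ref_t) + "TTT", tail_ref_t, "26S")
    assert call is not None
    assert call.templated_ext == 1
    assert call.tail == "TT" and call.tail_class == "oligoU"
    assert call.ambiguous_boundary


def test_call_tail_trimmed_end_with_oligou2(tail_ref_gc):
    # fragment ends 2 nt before the mature end; mid was built to end "ACG"
    # so the trim point is unambiguous
    call = call_tail(_frag(tail_ref_gc, trim=-2) + "TT", tail_ref_gc, "26S")
    assert call is not None
    assert call.end_offset == -2
    assert call.tail == "TT" and call.tail_class == "oligoU"


def test_call_tail_mono_classes(tail_ref_gc):
    for base, cls in (("A", "mono_A"), ("C", "mono_C"), ("T", "mono_U")):
        call = call_tail(_frag(tail_ref_gc) + base, tail_ref_gc, "26S")
        assert call is not None and call.tail_class == cls


def test_call_tail_mixed(tail_ref_gc):
    call = call_tail(_frag(tail_ref_gc) + "TAT", tail_ref_gc, "26S")
    assert call is not None and call.tail_class == "mixed"


def test_call_tail_unalignable_insert_rejected(tail_ref_gc):
    assert call_tail(_rand(60), tail_ref_gc, "26S") is None


def test_call_tail_interior_mismatch_tolerated(tail_ref_gc):
    frag = _frag(tail_ref_gc)
    corrupted = frag[:30] + ("A" if frag[30] != "A" else "C") + frag[31:]
    call = call_tail(corrupted + "TT", tail_ref_gc, "26S", max_mismatch=2)
    assert call is not None
    assert call.tail == "TT" and call.end_offset == 0


def test_classify_tail_rules():
    assert classify_tail("") == "no_tail"
    assert classify_tail("T") == "mono_U"
    assert classify_tail("G") == "mono_G"
    assert classify_tail("TTT") == "oligoU"
    assert classify_tail("TTA") == "mixed"


# ---------------------------------------------------------------------------
# full per-read flow, orientation autodetection


def test_run_tailseq_autodetects_orientation(tail_ref_gc):
    frag = _frag(tail_ref_gc)
    fwd = SmallRead("f", frag + "TT" + DEFAULT_LINKERS["linker-1"])
    rev = SmallRead("r", revcomp(frag + "TT" + DEFAULT_LINKERS["linker-1"]))
    calls, log = run_tailseq([fwd, rev], tail_ref_gc)
    assert log["assigned"] == 2
    assert all(c.tail == "TT" and c.linker_id == "linker-1" for c in calls)


# ---------------------------------------------------------------------------
# aggregation and comparison


def _calls(n_oligo: int, n_total: int = 100) -> list[TailCall]:
    calls = [
        TailCall("r", "26S", "linker-1", 0, 0, "TTT", "oligoU") for _ in range(n_oligo)
    ]
    calls += [
        TailCall("r", "26S", "linker-1", 0, 0, "", "no_tail") for _ in range(n_total - n_oligo)
    ]
    return calls


def test_summarize_tails_mean_sd():
    summary = summarize_tails(
        {"rep1": _calls(10), "rep2": _calls(12), "rep3": _calls(14)}, sample_id="s"
    )
    assert summary.n_assigned == 300
    assert summary.class_mean["oligoU"] == pytest.approx(0.12)
    assert summary.class_sd["oligoU"] == pytest.approx(0.02)
    # counts per replicate preserved for the 10/12/14 fixture
    assert [summary.per_replicate_counts[r]["oligoU"] for r in summary.replicate_ids] == [10, 12, 14]
    assert summary.oligoU_by_len == {"3": 36}


def test_summarize_tails_single_replicate_sd_absent():
    summary = summarize_tails({"rep1": _calls(5)})
    assert summary.class_sd["oligoU"] is None


def test_summarize_tails_all_no_tail():
    summary = summarize_tails({"rep1": _calls(0), "rep2": _calls(0)})
    assert summary.class_mean["oligoU"] == 0.0
    assert summary.oligoU_by_len == {}


def test_summarize_tails_excludes_empty_replicate():
    with pytest.warns(UserWarning, match="zero assigned"):
        summary = summarize_tails({"rep1": _calls(10), "rep2": []})
    assert summary.excluded_replicates == ["rep2"]
    assert summary.replicate_ids == ["rep1"]


def test_compare_conditions_identical_gives_p1():
    a = summarize_tails({"r1": _calls(10), "r2": _calls(10)})
    diff, p = compare_conditions(a, a, "oligoU")
    assert diff == 0.0
    assert p == 1.0


def test_compare_conditions_matches_textbook_t():
    a = summarize_tails({"r1": _calls(10), "r2": _calls(12), "r3": _calls(14)})
    b = summarize_tails({"r1": _calls(30), "r2": _calls(32), "r3": _calls(34)})
    diff, p = compare_conditions(a, b, "oligoU")
    assert diff == pytest.approx(-0.20)
    assert p == pytest.approx(ttest_two_tailed([0.10, 0.12, 0.14], [0.30, 0.32, 0.34]))
    assert p is not None and p < 0.001


def test_compare_conditions_single_replicate_no_p():
    a = summarize_tails({"r1": _calls(10), "r2": _calls(12)})
    b = summarize_tails({"r1": _calls(30)})
    diff, p = compare_conditions(a, b, "oligoU")
    assert p is None and diff == pytest.approx(0.11 - 0.30)
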