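"""Targeted rRNA 3' tail-seq: demultiplexing, tail calling, aggregation.

Tail-seq reads have the structure

    [rRNA 3' fragment, anchored at a gene-specific forward primer]
    [optional untemplated tail]
    [barcoded 3' linker]

Processing per read:

1. :func:`find_linker` locates the ligated linker (left-most occurrence,
   fewest mismatches; a >=10 nt linker prefix is accepted at the read
   end) and yields the insert 5' of it plus the linker identity, which
   doubles as the sample barcode;
2. :func:`check_forward_primer` verifies that the insert starts with the
   26S or 5.8S forward primer (auto mode tries both and rejects
   ambiguous inserts);
3. :func:`call_tail` aligns the insert to the rRNA 3' region and decides
   where templated sequence ends: bases matching the reference past the
   annotated mature 3' end are treated as templated precursor
   read-through (greedy maximal extension), and only the residue is the
   untemplated tail, classified as no_tail / mono_A/C/G/U / oligoU(k>=2)
   / mixed. A boundary whose last templated base is a U is flagged
   ambiguous, since an untemplated U run can be absorbed by a
   genomically templated U.

Mismatch tolerance (sequencing/PCR errors) applies only to the insert
interior: within a guard window before the boundary (maximum assayed 3'
trimming plus 3 nt) matching is exact, so errors near the boundary
reject or shorten the call rather than silently misclassify it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .reference_io import RrnaReference, SmallRead, revcomp
from . import stats as _stats

#: Barcoded 3' RNA linkers (DNA form); linker identity = sample identity.
DEFAULT_LINKERS: dict[str, str] = {
    "linker-1": "GATCCACACTCGGGCACCAAGGATTTAACCGCGAATTCCAGC",
    "linker-2": "CGACACACTCGGGCACCAAGGATTTAACCGCGAATTCCAGC",
    "linker-3": "GTACCACACTCGGGCACCAAGGATTTAACCGCGAATTCCAGC",
}

#: Universal RT primer complementary to the common linker core.
RT_PRIMER = "GCTGGAATTCGCGGTTAAATCCTTGGTGCCCGAGTGT"

#: Gene-specific forward PCR primers anchoring the rRNA 3' fragment.
FORWARD_PRIMERS: dict[str, str] = {
    "26S": "CAGATCACTCTGGTTCAATGTC",
    "5.8S": "GGTTGCATCGAGTATCGATGAA",
}

TAIL_CLASSES = ("no_tail", "mono_A", "mono_C", "mono_G", "mono_U", "oligoU", "mixed")

#: Exact-match protection window before the templated/untemplated boundary.
BOUNDARY_PROTECT = 3
#: Longest untemplated tail the caller will report; longer residues mean
#: the insert did not align cleanly and the read is rejected instead.
MAX_TAIL = 8
#: Minimum templated bases required to accept an anchoring.
MIN_TEMPLATED = 15


def split_templated_tail(
    observed: str,
    template: str,
    max_mismatch: int = 2,
    protect: int = BOUNDARY_PROTECT,
) -> tuple[int, int, str]:
    """Split an observed sequence into templated prefix and untemplated tail.

    Returns ``(b, mismatches, tail)`` where ``b`` is the *maximal* length
    of the templated prefix such that it carries at most ``max_mismatch``
    substitutions against ``template`` and its last ``protect`` bases
    match exactly. The exact-match window keeps the bases that decide the
    boundary free of mismatch tolerance, so sequencing errors right at
    the boundary shorten or reject the call instead of silently
    reclassifying the tail. The same function computes the simulator's
    expected calls, making the greedy rule a single source of truth.
    """
    jmax = min(len(observed), len(template))
    mm_prefix = [0] * (jmax + 1)
    match = [False] * jmax
    for j in range(jmax):
        eq = observed[j] == template[j]
        match[j] = eq
        mm_prefix[j + 1] = mm_prefix[j] + (0 if eq else 1)
    b = 0
    for cand in range(jmax, -1, -1):
        if mm_prefix[cand] > max_mismatch:
            continue
        lo = max(0, cand - protect)
        if all(match[lo:cand]):
            b = cand
            break
    return b, mm_prefix[b], observed[b:]


def _common_suffix(seqs: Sequence[str]) -> str:
    rev = [s[::-1] for s in seqs]
    k = 0
    while all(len(r) > k for r in rev) and len({r[k] for r in rev}) == 1:
        k += 1
    return seqs[0][len(seqs[0]) - k :] if k else ""


@dataclass
class LinkerSet:
    """Linkers, RT primer and forward primers used by one library design."""

    linkers: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LINKERS))
    rt_primer: str = RT_PRIMER
    forward_primers: dict[str, str] = field(default_factory=lambda: dict(FORWARD_PRIMERS))

    def __post_init__(self) -> None:
        seqs = list(self.linkers.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("linker sequences must be pairwise distinct")
        core = _common_suffix(seqs)
        if len(core) < 10:
            raise ValueError("linkers do not share a common core (>=10 nt)")
        self.core = core


def classify_tail(tail: str) -> str:
    """Classify an untemplated tail (DNA alphabet; U reported for T)."""
    if not tail:
        return "no_tail"
    if len(tail) == 1:
        return "mono_" + tail.replace("T", "U")
    if set(tail) == {"T"}:
        return "oligoU"
    return "mixed"


# ---------------------------------------------------------------------------
# demultiplexing


def _hamming_within(a: str, b: str, budget: int) -> int | None:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > budget:
                return None
    return mm


def find_linker(
    read: SmallRead, ls: LinkerSet | None = None, max_mismatch: int = 2
) -> tuple[str, str] | None:
    """Locate the ligated 3' linker; return (insert, linker_id) or None.

    The best occurrence is the left-most one within the mismatch budget;
    at equal offset the linker with fewest mismatches wins. A partial
    occurrence is accepted at the read end when at least 10 nt of the
    linker prefix remain, with the budget scaled to the overlap.
    """
    ls = ls or LinkerSet()
    seq = read.seq
    L = len(seq)
    for i in range(L):
        if L - i < 10:
            break
        best: tuple[int, str] | None = None
        for lid, linker in ls.linkers.items():
            ovl = min(len(linker), L - i)
            if ovl < len(linker) and ovl < 10:
                continue
            budget = max_mismatch if ovl == len(linker) else (max_mismatch * ovl) // len(linker)
            mm = _hamming_within(seq[i : i + ovl], linker[:ovl], budget)
            if mm is not None and (best is None or mm < best[0]):
                best = (mm, lid)
        if best is not None:
            return seq[:i], best[1]
    return None


def check_forward_primer(
    insert: str,
    ls: LinkerSet | None = None,
    rRNA_id: str | None = None,
    max_mismatch: int = 1,
) -> tuple[str, str] | None:
    """Verify the insert starts with a forward primer; return (insert, rRNA_id).

    With ``rRNA_id=None`` (auto mode) both primers are tested; an insert
    matching both is ambiguous and rejected. Returns None on rejection.
    """
    ls = ls or LinkerSet()
    candidates = [rRNA_id] if rRNA_id else list(ls.forward_primers)
    hits = []
    for rid in candidates:
        primer = ls.forward_primers[rid]
        if len(insert) >= len(primer):
            if _hamming_within(insert[: len(primer)], primer, max_mismatch) is not None:
                hits.append(rid)
    if len(hits) != 1:
        return None
    return insert, hits[0]


# ---------------------------------------------------------------------------
# tail calling


@dataclass
class TailCall:
    """Per-read decision about the rRNA 3' end.

    ``end_offset`` is signed relative to the annotated mature 3' end
    (0 = reaches the end exactly, -k = trimmed by k); ``templated_ext``
    counts post-end bases matching the downstream genomic sequence;
    ``tail`` is the remaining untemplated suffix.
    """

    read_id: str
    rRNA_id: str
    linker_id: str
    end_offset: int
    templated_ext: int
    tail: str
    tail_class: str
    ambiguous_boundary: bool = False

    def __post_init__(self) -> None:
        assert (self.tail == "") == (self.tail_class == "no_tail")


def _anchor_candidates(insert: str, T: str, E: int, k: int = 12) -> set[int]:
    """Candidate anchor positions of the insert 5' end on the transcript.

    Exact k-mer seeds at insert offsets 0, k, 2k tolerate up to two
    substitutions in the first 3k bases (pigeonhole).
    """
    cands: set[int] = set()
    for off in (0, k, 2 * k):
        if off + k > len(insert):
            break
        seed = insert[off : off + k]
        pos = T.find(seed)
        while pos != -1:
            if pos - off >= 0 and pos - off < E:
                cands.add(pos - off)
            pos = T.find(seed, pos + 1)
    return cands


def call_tail(
    insert: str,
    ref: RrnaReference,
    rRNA_id: str,
    max_mismatch: int = 2,
    linker_id: str = "",
    read_id: str = "",
) -> TailCall | None:
    """Align the insert to the rRNA 3' region and call its tail.

    The insert is anchored by exact seeds, then split by
    :func:`split_templated_tail` into a maximal templated prefix (up to
    ``max_mismatch`` interior substitutions, none within the last
    BOUNDARY_PROTECT bases) and the untemplated tail. Anchorings leaving
    fewer than MIN_TEMPLATED templated bases or a tail longer than
    MAX_TAIL are rejected (returns None, unassigned) rather than called.
    """
    feat = ref.feature(rRNA_id)
    if feat is None:
        raise ValueError(f"reference has no feature {rRNA_id}")
    T = ref.seq(feat.transcript_id)
    E = feat.end

    best: tuple[int, int, int] | None = None  # (templated_len, -mismatches, anchor)
    for p in _anchor_candidates(insert, T, E):
        b, mm, tail = split_templated_tail(insert, T[p:], max_mismatch)
        if b < MIN_TEMPLATED or len(tail) > MAX_TAIL:
            continue
        if best is None or (b, -mm) > (best[0], -best[1]):
            best = (b, mm, p)

    if best is None:
        return None
    b, _, p = best
    tail = insert[b:]
    boundary = p + b
    end_offset = min(boundary, E) - E
    templated_ext = max(0, boundary - E)
    ambiguous = b > 0 and insert[b - 1] == "T"
    return TailCall(
        read_id=read_id,
        rRNA_id=rRNA_id,
        linker_id=linker_id,
        end_offset=end_offset,
        templated_ext=templated_ext,
        tail=tail,
        tail_class=classify_tail(tail),
        ambiguous_boundary=ambiguous,
    )


def run_tailseq(
    reads: Iterable[SmallRead],
    ref: RrnaReference,
    ls: LinkerSet | None = None,
    rRNA_id: str | None = None,
    linker_max_mismatch: int = 2,
    primer_max_mismatch: int = 1,
    max_mismatch: int = 2,
) -> tuple[list[TailCall], dict[str, int]]:
    """Demultiplex, verify and call every read; auto-detects orientation.

    Returns (calls, log) where log counts input/assigned reads and the
    reasons reads were dropped.
    """
    ls = ls or LinkerSet()
    calls: list[TailCall] = []
    log = {"input": 0, "assigned": 0, "no_linker": 0, "no_primer": 0, "no_alignment": 0}
    for read in reads:
        log["input"] += 1
        outcome = None
        for seq in (read.seq, revcomp(read.seq)):
            hit = find_linker(SmallRead(read.id, seq), ls, linker_max_mismatch)
            if hit is None:
                outcome = outcome or "no_linker"
                continue
            insert, linker_id = hit
            ver = check_forward_primer(insert, ls, rRNA_id, primer_max_mismatch)
            if ver is None:
                outcome = "no_primer"
                continue
            insert, rid = ver
            call = call_tail(
                insert, ref, rid, max_mismatch, linker_id=linker_id, read_id=read.id
            )
            if call is None:
                outcome = "no_alignment"
                continue
            calls.append(call)
            outcome = "assigned"
            break
        log[outcome or "no_linker"] += 1
    return calls, log


# ---------------------------------------------------------------------------
# aggregation


def _oligo_len_key(k: int) -> str:
    return str(k) if k <= 5 else "6+"


@dataclass
class TailSummary:
    """Per-sample tail-class counts with replicate mean and SD.

    ``oligoU_by_len`` pools mono-U (k=1) with oligo-U (k>=2) into a
    1..6+ uridine-run-length histogram summed over replicates. Fractions
    are per replicate over its assigned reads; mean/SD (sample SD, n-1)
    are across replicates. Replicates with zero assigned reads are
    excluded from the statistics and listed in ``excluded_replicates``.
    """

    sample_id: str
    rRNA_id: str
    n_assigned: int = 0
    replicate_ids: list[str] = field(default_factory=list)
    per_replicate_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    per_replicate_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    class_mean: dict[str, float] = field(default_factory=dict)
    class_sd: dict[str, float | None] = field(default_factory=dict)
    oligoU_by_len: dict[str, int] = field(default_factory=dict)
    excluded_replicates: list[str] = field(default_factory=list)

    def fraction_vector(self, tail_class: str) -> list[float]:
        return [self.per_replicate_fractions[r][tail_class] for r in self.replicate_ids]


def summarize_tails(
    replicates: dict[str, list[TailCall]],
    sample_id: str = "sample",
    rRNA_id: str | None = None,
) -> TailSummary:
    """Aggregate per-replicate tail calls into a :class:`TailSummary`."""
    rid = rRNA_id
    summary = TailSummary(sample_id=sample_id, rRNA_id=rid or "")
    for rep_id in replicates:
        calls = replicates[rep_id]
        if not calls:
            warnings.warn(
                f"{sample_id}/{rep_id}: zero assigned reads; replicate excluded from mean/SD"
            )
            summary.excluded_replicates.append(rep_id)
            continue
        if rid is None:
            rid = calls[0].rRNA_id
            summary.rRNA_id = rid
        counts = {c: 0 for c in TAIL_CLASSES}
        for call in calls:
            counts[call.tail_class] += 1
            if call.tail_class == "mono_U":
                key = _oligo_len_key(1)
                summary.oligoU_by_len[key] = summary.oligoU_by_len.get(key, 0) + 1
            elif call.tail_class == "oligoU":
                key = _oligo_len_key(len(call.tail))
                summary.oligoU_by_len[key] = summary.oligoU_by_len.get(key, 0) + 1
        n = len(calls)
        summary.n_assigned += n
        summary.replicate_ids.append(rep_id)
        summary.per_replicate_counts[rep_id] = counts
        summary.per_replicate_fractions[rep_id] = {c: counts[c] / n for c in TAIL_CLASSES}
    for c in TAIL_CLASSES:
        vec = [summary.per_replicate_fractions[r][c] for r in summary.replicate_ids]
        if vec:
            mean, sd = _stats.mean_sd(vec)
            summary.class_mean[c] = mean
            summary.class_sd[c] = sd
    return summary


def uridylated_fraction_vector(summary: TailSummary) -> list[float]:
    """Per-replicate fraction of reads with any untemplated U tail."""
    return [
        summary.per_replicate_fractions[r]["mono_U"] + summary.per_replicate_fractions[r]["oligoU"]
        for r in summary.replicate_ids
    ]


def compare_conditions(
    a: TailSummary,
    b: TailSummary,
    class_selector: str | Callable[[TailSummary], list[float]] = "oligoU",
) -> tuple[float, float | None]:
    """Effect and two-tailed t-test p-value between two conditions.

    ``class_selector`` is a tail-class name or a callable mapping a
    summary to its per-replicate fraction vector. The p-value is absent
    (None) when either condition has fewer than two usable replicates.
    """
    if callable(class_selector):
        va, vb = class_selector(a), class_selector(b)
    else:
        va, vb = a.fraction_vector(class_selector), b.fraction_vector(class_selector)
    diff = float(np.mean(va) - np.mean(vb)) if va and vb else math.nan
    if len(va) < 2 or len(vb) < 2:
        return diff, None
    return diff, _stats.ttest_two_tailed(va, vb)
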