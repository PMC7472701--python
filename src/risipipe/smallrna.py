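"""Small-RNA pipeline: trimming, alignment, classification, quantification.

Implements the processing applied to 18-30 nt small-RNA libraries:

1. 3' adaptor trimming (left-most occurrence within a mismatch budget,
   including a partial adaptor prefix at the read end);
2. length filtering to 18-30 nt inclusive;
3. alignment of the insert to the reference transcript set on both
   strands, with a bounded number of internal mismatches and up to a few
   unmatched 3' bases ("soft tail", which carries untemplated additions);
4. classification into sense rRNA fragments, antisense ribosomal siRNAs
   (risiRNAs), other mapped reads, and unmapped reads;
5. quantification with the rRNA-exclusion normalizer: reads per million
   are computed over (total mapped reads) minus (sense reads in mature
   5S/5.8S/18S/26S), so that sense-rRNA degradation fragments cannot
   dilute the risiRNA signal;
6. per-region risiRNA counts over the pre-rRNA transcription unit, size
   and 5'-nucleotide profiles, and counting of untemplated 3' uridylation.

The aligner is a deterministic exact-seed + extension aligner that
reports *all* placements within the mismatch/soft-tail budget; on small
references it is equivalent to an exhaustive all-positions scan (a
property the test suite enforces against an independent oracle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .reference_io import (
    MATURE_RRNAS,
    FeatureInterval,
    RrnaReference,
    SmallRead,
    revcomp,
)

#: 3' adaptor ligated to small RNAs (DNA form of the RNA adaptor
#: pUCGUAUGCCGUCUUCUGCUUG-idT).
ADAPTOR_3P = "TCGTATGCCGTCTTCTGCTTG"

SENSE = "sense"
ANTISENSE = "antisense"

# read classes
SENSE_RRNA = "sense_rRNA"
RISIRNA = "risiRNA"
OTHER_MAPPED = "other_mapped"
UNMAPPED = "unmapped"
CLASSES = (SENSE_RRNA, RISIRNA, OTHER_MAPPED, UNMAPPED)


# ---------------------------------------------------------------------------
# trimming and filtering


def trim_3p_adaptor(
    read: SmallRead,
    adaptor: str = ADAPTOR_3P,
    min_overlap: int = 5,
    max_mismatch: int = 1,
) -> SmallRead | None:
    """Trim the 3' adaptor; return the insert, or None if no adaptor found.

    The insert is everything 5' of the left-most adaptor occurrence whose
    Hamming distance is within ``max_mismatch``. A partial occurrence is
    accepted at the read end when at least ``min_overlap`` bases of the
    adaptor prefix remain, with the mismatch budget scaled down
    proportionally to the overlap.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    if min_overlap < 5:
        raise ValueError("min_overlap must be >= 5")
    seq = read.seq
    L = len(seq)
    alen = len(adaptor)

    # fast path: left-most exact occurrence bounds the scan
    exact = seq.find(adaptor)
    limit = exact if exact >= 0 else L

    for i in range(limit):
        ovl = min(alen, L - i)
        if ovl < alen and ovl < min_overlap:
            break
        allowed = max_mismatch if ovl == alen else (max_mismatch * ovl) // alen
        mm = 0
        ok = True
        window = seq[i : i + ovl]
        for a, b in zip(window, adaptor):
            if a != b:
                mm += 1
                if mm > allowed:
                    ok = False
                    break
        if ok:
            return SmallRead(read.id, seq[:i], read.qual[:i] if read.qual else None)
    if exact >= 0:
        return SmallRead(read.id, seq[:exact], read.qual[:exact] if read.qual else None)
    return None


def length_filter(read: SmallRead, lo: int = 18, hi: int = 30) -> bool:
    """Keep a trimmed read iff lo <= length <= hi (both inclusive)."""
    return lo <= len(read.seq) <= hi


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class SmallAlignment:
    """Placement of a read on a transcript.

    ``start``/``end`` are 0-based half-open on the sense strand of the
    transcript regardless of read strand. ``soft_tail`` holds the 3'
    bases of the *read* left unmatched (candidates for untemplated
    additions).
    """

    read_id: str
    transcript_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    soft_tail: str = ""


class ReadAligner:
    """Exact-seed + extension aligner over a small transcript set.

    Reports every placement (both strands) whose matched span carries at
    most ``max_mismatch`` mismatches, allowing up to ``allow_soft_tail``
    unmatched 3' bases; at each position the soft tail is minimal
    (maximal templated span). Seeds are chosen by the pigeonhole
    principle over the 5' core of the read that is guaranteed to be part
    of the matched span, so no placement within budget can be missed for
    reads of at least ``min_read_len`` bases; shorter reads fall back to
    a direct scan.
    """

    def __init__(
        self,
        ref: RrnaReference,
        max_mismatch: int = 0,
        allow_soft_tail: int = 4,
        min_read_len: int = 18,
    ) -> None:
        if not ref.transcripts:
            raise ValueError("empty reference")
        if max_mismatch < 0 or allow_soft_tail < 0:
            raise ValueError("negative parameter")
        self.ref = ref
        self.max_mismatch = max_mismatch
        self.allow_soft_tail = allow_soft_tail
        self.min_read_len = min_read_len
        core = min_read_len - allow_soft_tail
        self.n_seeds = max_mismatch + 1
        self.k = max(1, core // self.n_seeds)
        if self.k * self.n_seeds > max(1, core):
            # pigeonhole cannot be guaranteed; everything uses the scan path
            self.k = 0

        # oriented sequences: (transcript_id, strand, sequence)
        self.oriented: list[tuple[str, str, str]] = []
        for tid, seq in ref.transcripts.items():
            self.oriented.append((tid, SENSE, seq))
            self.oriented.append((tid, ANTISENSE, revcomp(seq)))

        self.index: dict[str, list[tuple[int, int]]] = {}
        if self.k:
            k = self.k
            for oi, (_, _, s) in enumerate(self.oriented):
                for pos in range(len(s) - k + 1):
                    self.index.setdefault(s[pos : pos + k], []).append((oi, pos))

    # -- placement verification -------------------------------------------

    def _verify(self, seq: str, s: str, p: int) -> tuple[int, int] | None:
        """Minimal-soft-tail placement of seq at position p of oriented s.

        Returns (soft_tail_len, mismatches) or None.
        """
        L = len(seq)
        N = len(s)
        if p < 0:
            return None
        for t in range(self.allow_soft_tail + 1):
            span = L - t
            if span < 1:
                return None
            if p + span > N:
                continue
            mm = 0
            ok = True
            for j in range(span):
                if seq[j] != s[p + j]:
                    mm += 1
                    if mm > self.max_mismatch:
                        ok = False
                        break
            if ok:
                return t, mm
        return None

    def _candidates(self, seq: str) -> set[tuple[int, int]]:
        L = len(seq)
        core = L - self.allow_soft_tail
        if not self.k or core < self.k * self.n_seeds:
            # direct scan over all positions
            cands: set[tuple[int, int]] = set()
            for oi, (_, _, s) in enumerate(self.oriented):
                for p in range(len(s) - max(1, core) + 1):
                    cands.add((oi, p))
            return cands
        cands = set()
        k = self.k
        # n_seeds disjoint chunks spread over the guaranteed core
        for j in range(self.n_seeds):
            off = (j * (core - k)) // max(1, self.n_seeds - 1) if self.n_seeds > 1 else 0
            for oi, pos in self.index.get(seq[off : off + k], ()):
                cands.add((oi, pos - off))
        return cands

    def align_read(self, read: SmallRead) -> list[SmallAlignment]:
        seq = read.seq
        if not seq:
            return []
        out: list[SmallAlignment] = []
        for oi, p in self._candidates(seq):
            tid, strand, s = self.oriented[oi]
            hit = self._verify(seq, s, p)
            if hit is None:
                continue
            t, mm = hit
            span = len(seq) - t
            tail = seq[span:]
            if strand == SENSE:
                start, end = p, p + span
            else:
                tlen = len(s)
                start, end = tlen - p - span, tlen - p
            out.append(SmallAlignment(read.id, tid, start, end, strand, mm, tail))
        order = {tid: i for i, tid in enumerate(self.ref.transcript_order)}
        out.sort(key=lambda a: (order[a.transcript_id], a.start, a.strand, a.end))
        return out


def align_reads(
    reads: Iterable[SmallRead],
    ref: RrnaReference,
    max_mismatch: int = 0,
    allow_soft_tail: int = 4,
) -> list[list[SmallAlignment]]:
    """Align each read; returns one (possibly empty) alignment list per read."""
    aligner = ReadAligner(ref, max_mismatch=max_mismatch, allow_soft_tail=allow_soft_tail)
    return [aligner.align_read(r) for r in reads]


def alignments_from_sam(path, ref: RrnaReference) -> dict[str, list[SmallAlignment]]:
    """Import alignments from a SAM file produced by an external aligner.

    Soft tails are taken from a trailing soft clip on the read's 3' end
    (which is the cigar's leading clip for reverse-strand placements);
    mismatch counts from the NM tag when present.
    """
    import pysam

    out: dict[str, list[SmallAlignment]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                out.setdefault(rec.query_name, [])
                continue
            strand = ANTISENSE if rec.is_reverse else SENSE
            cig = rec.cigartuples or []
            tail = ""
            qseq = rec.query_sequence or ""
            if not rec.is_reverse:
                if cig and cig[-1][0] == 4:  # trailing S
                    tail = qseq[len(qseq) - cig[-1][1] :]
            else:
                if cig and cig[0][0] == 4:  # leading S = read 3' end
                    tail = revcomp(qseq[: cig[0][1]])
            mm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.setdefault(rec.query_name, []).append(
                SmallAlignment(
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    strand,
                    int(mm),
                    tail,
                )
            )
    return out


# ---------------------------------------------------------------------------
# classification


def _majority_feature(
    aln: SmallAlignment, feats: Sequence[FeatureInterval]
) -> FeatureInterval | None:
    """Feature containing the majority of the aligned span.

    Ties go to the 5'-most region of the sense transcript (smallest
    start). Returns None when the span overlaps no feature.
    """
    best: FeatureInterval | None = None
    best_ovl = 0
    for f in feats:
        ovl = f.overlap(aln.start, aln.end)
        if ovl > best_ovl or (ovl == best_ovl and ovl > 0 and best and f.start < best.start):
            best, best_ovl = f, ovl
    return best if best_ovl > 0 else None


def _best_alignment(
    alignments: Sequence[SmallAlignment], ref: RrnaReference
) -> SmallAlignment:
    order = {tid: i for i, tid in enumerate(ref.transcript_order)}
    return min(
        alignments,
        key=lambda a: (a.mismatches, len(a.soft_tail), order[a.transcript_id], a.start, a.strand),
    )


def classify_read(alignments: Sequence[SmallAlignment], ref: RrnaReference) -> str:
    """Assign one of the four read classes.

    Priority: risiRNA > sense_rRNA > other_mapped. Any accepted antisense
    placement on a transcript carrying rRNA features makes the read a
    risiRNA; otherwise the best placement decides. A sense placement is
    sense_rRNA only when the majority of its span lies in a mature rRNA
    (5S, 5.8S, 18S, 26S); sense reads mostly in spacers are other_mapped
    (counted separately in the summary).
    """
    if not alignments:
        return UNMAPPED
    rrna_tids = ref.rrna_transcript_ids
    if any(a.strand == ANTISENSE and a.transcript_id in rrna_tids for a in alignments):
        return RISIRNA
    best = _best_alignment(alignments, ref)
    if best.strand == SENSE and best.transcript_id in rrna_tids:
        f = _majority_feature(best, ref.features_of(best.transcript_id))
        if f is not None and f.name in MATURE_RRNAS:
            return SENSE_RRNA
    return OTHER_MAPPED


# ---------------------------------------------------------------------------
# counting


@dataclass
class CountSummary:
    """Per-sample class counts and the rRNA-exclusion normalizer.

    ``risiRNA`` counts antisense reads on the pre-rRNA transcription
    unit; antisense-to-5S reads are reported separately (``risiRNA_5S``)
    and never merged into the default per-million numerator.
    ``norm_denominator`` is total mapped reads minus sense mature-rRNA
    reads, excluding sense-rRNA degradation fragments from the scale.
    """

    sample_id: str
    total_clean: int = 0
    total_mapped: int = 0
    sense_rRNA: int = 0
    sense_spacer: int = 0
    risiRNA: int = 0
    risiRNA_5S: int = 0
    other_mapped: int = 0
    unmapped: int = 0
    norm_denominator: int = 0
    zero_denominator: bool = False
    per_transcript: dict[str, float] = field(default_factory=dict)
    per_region: dict[str, int] = field(default_factory=dict)

    @property
    def risiRNA_total(self) -> int:
        return self.risiRNA + self.risiRNA_5S


def _region_of_risirna(
    alignments: Sequence[SmallAlignment], ref: RrnaReference
) -> str | None:
    """Region assignment for a risiRNA read (majority rule, 5'-most ties)."""
    unit = ref.unit_transcript_ids
    anti = [a for a in alignments if a.strand == ANTISENSE and a.transcript_id in unit]
    if not anti:
        return None
    best = _best_alignment(anti, ref)
    f = _majority_feature(best, ref.features_of(best.transcript_id))
    return f.name if f else None


def summarize_counts(
    classified: Iterable[tuple[SmallRead, Sequence[SmallAlignment], str]],
    ref: RrnaReference,
    sample_id: str = "sample",
) -> CountSummary:
    """Aggregate classified reads into a :class:`CountSummary`.

    ``classified`` yields ``(read, alignments, read_class)`` triples.
    Per-transcript counts assign 1/k to each of the k best placements of
    a multi-mapping read. The normalization denominator is computed
    exactly as total mapped reads minus sense mature-rRNA reads.
    """
    cs = CountSummary(sample_id=sample_id)
    unit = ref.unit_transcript_ids
    for read, alns, cls in classified:
        cs.total_clean += 1
        if cls == UNMAPPED:
            cs.unmapped += 1
            continue
        cs.total_mapped += 1
        # fractional per-transcript counting over best-tier placements
        if alns:
            best = _best_alignment(alns, ref)
            tier = [
                a
                for a in alns
                if (a.mismatches, len(a.soft_tail)) == (best.mismatches, len(best.soft_tail))
            ]
            w = 1.0 / len(tier)
            for a in tier:
                cs.per_transcript[a.transcript_id] = cs.per_transcript.get(a.transcript_id, 0.0) + w
        if cls == SENSE_RRNA:
            cs.sense_rRNA += 1
        elif cls == RISIRNA:
            if any(a.strand == ANTISENSE and a.transcript_id in unit for a in alns):
                cs.risiRNA += 1
                region = _region_of_risirna(alns, ref)
                if region:
                    cs.per_region[region] = cs.per_region.get(region, 0) + 1
            else:
                cs.risiRNA_5S += 1
        else:
            cs.other_mapped += 1
            best = _best_alignment(alns, ref)
            if best.strand == SENSE and best.transcript_id in ref.rrna_transcript_ids:
                cs.sense_spacer += 1
    cs.norm_denominator = cs.total_mapped - cs.sense_rRNA
    cs.zero_denominator = cs.norm_denominator == 0
    return cs


def risirna_rpm(cs: CountSummary, include_5s: bool = False) -> float:
    """risiRNA reads per million of the rRNA-exclusion denominator."""
    if cs.norm_denominator <= 0:
        raise ZeroDivisionError(
            f"sample {cs.sample_id}: normalization denominator is zero; "
            "per-million values are undefined"
        )
    num = cs.risiRNA_total if include_5s else cs.risiRNA
    return num * 1e6 / cs.norm_denominator


def fold_enrichment(
    a: CountSummary, b: CountSummary, pseudocount: float = 0.0, include_5s: bool = False
) -> float:
    """Ratio of risiRNA per-million abundances, a over b.

    With ``pseudocount`` > 0 the pseudocount is added to both risiRNA
    counts before scaling; otherwise a zero numerator in ``b`` yields
    ``inf`` (the pipeline never divides by zero silently).
    """
    if a.norm_denominator <= 0 or b.norm_denominator <= 0:
        raise ZeroDivisionError("normalization denominator is zero")
    ka = (a.risiRNA_total if include_5s else a.risiRNA) + pseudocount
    kb = (b.risiRNA_total if include_5s else b.risiRNA) + pseudocount
    rpm_a = ka * 1e6 / a.norm_denominator
    rpm_b = kb * 1e6 / b.norm_denominator
    if rpm_b == 0:
        return math.inf
    return rpm_a / rpm_b


def per_region_counts(
    classified: Iterable[tuple[SmallRead, Sequence[SmallAlignment], str]],
    ref: RrnaReference,
) -> dict[str, int]:
    """risiRNA counts per region of the pre-rRNA transcription unit.

    Each risiRNA read goes to the region containing the majority of its
    aligned span; ties go to the 5'-most region.
    """
    counts: dict[str, int] = {}
    for _, alns, cls in classified:
        if cls != RISIRNA:
            continue
        region = _region_of_risirna(alns, ref)
        if region:
            counts[region] = counts.get(region, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# profiles and uridylation


_PROFILE_COLS = ("A", "C", "G", "U")


def _profile_frame(counts: dict[tuple[int, str], int], lo: int, hi: int) -> pd.DataFrame:
    mat = pd.DataFrame(0, index=range(lo, hi + 1), columns=list(_PROFILE_COLS))
    mat.index.name = "length"
    for (L, first), n in counts.items():
        mat.loc[L, first] = n
    return mat


def size_firstnt_profile(reads: Iterable[SmallRead], lo: int = 18, hi: int = 30) -> pd.DataFrame:
    """Count matrix over (read length 18..30, 5' nucleotide A/C/G/U).

    Returns a pandas DataFrame indexed by length with columns A, C, G, U
    (DNA T reported as U). Reads outside the length range or starting
    with N are not counted.
    """
    counts: dict[tuple[int, str], int] = {}
    for r in reads:
        L = len(r.seq)
        if not (lo <= L <= hi) or not r.seq:
            continue
        first = r.seq[0].replace("T", "U")
        if first in _PROFILE_COLS:
            counts[(L, first)] = counts.get((L, first), 0) + 1
    return _profile_frame(counts, lo, hi)


def _antisense_template_continuation(
    aln: SmallAlignment, ref: RrnaReference, n: int
) -> str:
    """Template continuation past an antisense read's 3' end.

    The read's 3' end sits at the *left* edge of its transcript interval;
    the continuation is the reverse complement of the reference walking
    leftwards from ``start``.
    """
    seq = ref.seq(aln.transcript_id)
    left = seq[max(0, aln.start - n) : aln.start]
    return revcomp(left)


def count_untemplated_3U(
    risirna_alignments: Iterable[SmallAlignment],
    ref: RrnaReference,
) -> tuple[int, dict[int, int]]:
    """Count risiRNA reads carrying an untemplated 3' uridine tail.

    For each antisense alignment the 3' soft tail is first extended
    greedily against the template continuation (bases that match the
    genome are templated, not modifications); a read counts as uridylated
    iff the remaining tail is non-empty and consists only of U. Returns
    (uridylated read count, histogram keyed by untemplated tail length).
    """
    n_uridylated = 0
    hist: dict[int, int] = {}
    for aln in risirna_alignments:
        if aln.strand != ANTISENSE:
            continue
        tail = aln.soft_tail
        if not tail:
            continue
        cont = _antisense_template_continuation(aln, ref, len(tail))
        k = 0
        while k < len(tail) and k < len(cont) and tail[k] == cont[k]:
            k += 1
        rest = tail[k:]
        if rest and set(rest) == {"T"}:
            n_uridylated += 1
            hist[len(rest)] = hist.get(len(rest), 0) + 1
    return n_uridylated, hist


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class SmallRnaParams:
    """Tunable knobs of the small-RNA pipeline (defaults = study settings)."""

    adaptor: str = ADAPTOR_3P
    min_overlap: int = 5
    trim_max_mismatch: int = 1
    min_len: int = 18
    max_len: int = 30
    max_mismatch: int = 0
    allow_soft_tail: int = 4
    pseudocount: float = 0.0


@dataclass
class SmallRnaResult:
    summary: CountSummary
    profile: pd.DataFrame  # size x 5'-nt count matrix
    uridylated_risirna: int
    uridylation_hist: dict[int, int]
    filter_log: dict[str, int]


def run_smallrna(
    reads: Iterable[SmallRead],
    ref: RrnaReference,
    params: SmallRnaParams | None = None,
    sample_id: str = "sample",
    profile_class: str = RISIRNA,
) -> SmallRnaResult:
    """Full pipeline over a read iterable; single pass, constant memory.

    ``profile_class`` selects which read class enters the size/5'-nt
    profile (default: risiRNAs, the class whose 22G character the study
    examines).
    """
    params = params or SmallRnaParams()
    aligner = ReadAligner(
        ref, max_mismatch=params.max_mismatch, allow_soft_tail=params.allow_soft_tail
    )
    log = {"input": 0, "trimmed": 0, "length_pass": 0}
    cs = CountSummary(sample_id=sample_id)
    unit = ref.unit_transcript_ids
    profile_counts: dict[tuple[int, str], int] = {}
    n_urid = 0
    urid_hist: dict[int, int] = {}

    for raw in reads:
        log["input"] += 1
        insert = trim_3p_adaptor(
            raw, params.adaptor, params.min_overlap, params.trim_max_mismatch
        )
        if insert is None:
            continue
        log["trimmed"] += 1
        if not length_filter(insert, params.min_len, params.max_len):
            continue
        log["length_pass"] += 1
        alns = aligner.align_read(insert)
        cls = classify_read(alns, ref)

        cs.total_clean += 1
        if cls == UNMAPPED:
            cs.unmapped += 1
        else:
            cs.total_mapped += 1
            best = _best_alignment(alns, ref)
            tier = [
                a
                for a in alns
                if (a.mismatches, len(a.soft_tail)) == (best.mismatches, len(best.soft_tail))
            ]
            w = 1.0 / len(tier)
            for a in tier:
                cs.per_transcript[a.transcript_id] = cs.per_transcript.get(a.transcript_id, 0.0) + w
            if cls == SENSE_RRNA:
                cs.sense_rRNA += 1
            elif cls == RISIRNA:
                anti_unit = [
                    a for a in alns if a.strand == ANTISENSE and a.transcript_id in unit
                ]
                if anti_unit:
                    cs.risiRNA += 1
                    region = _region_of_risirna(alns, ref)
                    if region:
                        cs.per_region[region] = cs.per_region.get(region, 0) + 1
                    u, h = count_untemplated_3U([_best_alignment(anti_unit, ref)], ref)
                    n_urid += u
                    for k, v in h.items():
                        urid_hist[k] = urid_hist.get(k, 0) + v
                else:
                    cs.risiRNA_5S += 1
            else:
                cs.other_mapped += 1
                if best.strand == SENSE and best.transcript_id in ref.rrna_transcript_ids:
                    cs.sense_spacer += 1
        if cls == profile_class and insert.seq:
            L = len(insert.seq)
            first = insert.seq[0].replace("T", "U")
            if params.min_len <= L <= params.max_len and first in _PROFILE_COLS:
                profile_counts[(L, first)] = profile_counts.get((L, first), 0) + 1

    cs.norm_denominator = cs.total_mapped - cs.sense_rRNA
    cs.zero_denominator = cs.norm_denominator == 0
    profile = _profile_frame(profile_counts, params.min_len, params.max_len)
    return SmallRnaResult(cs, profile, n_urid, urid_hist, log)
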