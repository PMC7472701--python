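"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately share no code with the implementations they check:
the aligner oracle scans every position, strand and soft-tail length
with vectorized Hamming counts; the trimmer oracle scans every adaptor
offset with a plain Hamming loop.
"""

from __future__ import annotations

import numpy as np

from risipipe.reference_io import RrnaReference, revcomp


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def exhaustive_align_multi(
    read_seq: str,
    ref: RrnaReference,
    budgets: tuple[int, ...],
    allow_soft_tail: int,
) -> dict[int, set]:
    """All placements per mismatch budget by full scan.

    Returns, for each budget, the set of tuples
    (transcript_id, strand, start, end, mismatches, soft_tail) with the
    minimal soft tail at each position.
    """
    L = len(read_seq)
    out: dict[int, set] = {m: set() for m in budgets}
    r = np.frombuffer(read_seq.encode(), dtype=np.uint8)
    min_span = max(1, L - allow_soft_tail)

    for tid, seq in ref.transcripts.items():
        for strand, S in (("sense", seq), ("antisense", revcomp(seq))):
            s = np.frombuffer(S.encode(), dtype=np.uint8)
            N = len(S)

            def emit(m: int, p: int, t: int, mm: int) -> None:
                span = L - t
                if strand == "sense":
                    start, end = p, p + span
                else:
                    start, end = N - p - span, N - p
                out[m].add((tid, strand, start, end, mm, read_seq[span:]))

            # positions where the full read fits: vectorized prefix sums
            if N >= L:
                win = np.lib.stride_tricks.sliding_window_view(s, L)
                cum = (win != r).astype(np.int32).cumsum(axis=1)
                for m in budgets:
                    tmin = np.full(cum.shape[0], -1, dtype=np.int8)
                    for t in range(allow_soft_tail + 1):
                        span = L - t
                        if span < 1:
                            break
                        sel = (tmin == -1) & (cum[:, span - 1] <= m)
                        tmin[sel] = t
                    for p in np.flatnonzero(tmin >= 0):
                        t = int(tmin[p])
                        emit(m, int(p), t, int(cum[p, L - t - 1]))

            # boundary positions where only a shortened span fits
            p_lo = max(0, N - L + 1)
            p_hi = N - min_span
            for p in range(p_lo, p_hi + 1):
                done = {m: False for m in budgets}
                for t in range(allow_soft_tail + 1):
                    span = L - t
                    if span < 1 or p + span > N:
                        continue
                    mm = _hamming(read_seq[:span], S[p : p + span])
                    for m in budgets:
                        if not done[m] and mm <= m:
                            done[m] = True
                            emit(m, p, t, mm)
    return out


def alignment_tuples(alignments) -> set:
    """Canonical tuple form of SmallAlignment objects for set comparison."""
    return {
        (a.transcript_id, a.strand, a.start, a.end, a.mismatches, a.soft_tail)
        for a in alignments
    }


def brute_force_trim(seq: str, adaptor: str, min_overlap: int, max_mismatch: int) -> int | None:
    """Left-most adaptor offset by scanning every position; None if absent."""
    L, alen = len(seq), len(adaptor)
    for i in range(L):
        ovl = min(alen, L - i)
        if ovl < alen and ovl < min_overlap:
            return None
        allowed = max_mismatch if ovl == alen else (max_mismatch * ovl) // alen
        if _hamming(seq[i : i + ovl], adaptor[:ovl]) <= allowed:
            return i
    return None
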