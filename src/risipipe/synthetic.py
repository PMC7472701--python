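"""Synthetic reference and read libraries with per-read ground truth.

The generator emulates the two library types the pipeline analyses:

* small-RNA libraries dominated by 22 nt reads with a 5' G bias
  (22G-RNA-like), containing a configurable fraction of antisense
  ribosomal siRNAs (risiRNAs), sense-rRNA degradation fragments, decoy
  transcriptome reads and unmappable reads, with optional untemplated
  3' U runs on risiRNAs and the 3' adaptor appended to every read;

* targeted tail-seq libraries: a forward-primer-anchored sense fragment
  of the 26S or 5.8S 3' region, possibly trimmed a few bases short of
  the mature end, followed by a drawn tail (none, a single nucleotide,
  an oligo-U run, or a mixed tail) and a barcoded linker.

Every read carries a truth record. For tails the truth contains both the
drawn tail and the *expected call* under the greedy templated-extension
rule: drawn tail bases that coincide with the downstream genomic
sequence are absorbed as templated, exactly as the caller will absorb
them, so exact-recovery tests compare like with like and boundary
ambiguity is a labelled property rather than a source of flakiness.

One seeded generator drives all draws in a fixed order; identical
configurations produce byte-identical FASTQ and truth files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .reference_io import FeatureInterval, RrnaReference, SmallRead, revcomp, write_fastq, write_table
from .smallrna import ADAPTOR_3P
from .tailseq import DEFAULT_LINKERS, FORWARD_PRIMERS, classify_tail, split_templated_tail

UNIT_ORDER = ("ETS5", "18S", "ITS1", "5.8S", "ITS2", "26S", "ETS3")

DEFAULT_FEATURE_LENGTHS = {
    "ETS5": 100,
    "18S": 250,
    "ITS1": 80,
    "5.8S": 120,
    "ITS2": 90,
    "26S": 400,
    "ETS3": 120,
}

#: Offset of the embedded forward primer upstream of each mature 3' end.
PRIMER_OFFSET_FROM_END = {"26S": 60, "5.8S": 50}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def make_reference(
    seed: int = 0,
    lengths: dict[str, int] | None = None,
    five_s_len: int = 120,
    n_decoys: int = 2,
    decoy_len: int = 300,
) -> RrnaReference:
    """Random toy reference: pre-rRNA unit, 5S transcript, decoy mRNAs.

    The unit carries the ordered regions ETS5-18S-ITS1-5.8S-ITS2-26S-ETS3.
    The 26S and 5.8S forward primers are embedded at fixed offsets before
    the mature 3' ends so that tail-seq amplicons exist. Deterministic
    under ``seed``.
    """
    lens = dict(DEFAULT_FEATURE_LENGTHS)
    if lengths:
        lens.update(lengths)
    for name, L in lens.items():
        if L < 50:
            raise ValueError(f"feature {name}: length must be >= 50, got {L}")

    rng = np.random.default_rng(seed)
    parts: dict[str, str] = {name: _random_seq(rng, lens[name]) for name in UNIT_ORDER}
    # embed the gene-specific forward primers near the mature 3' ends
    for rid, offset in PRIMER_OFFSET_FROM_END.items():
        primer = FORWARD_PRIMERS[rid]
        seq = parts[rid]
        start = len(seq) - offset
        parts[rid] = seq[:start] + primer + seq[start + len(primer) :]

    features: list[FeatureInterval] = []
    pos = 0
    unit_seq = ""
    for name in UNIT_ORDER:
        seq = parts[name]
        features.append(FeatureInterval("pre-rRNA", name, pos, pos + len(seq)))
        unit_seq += seq
        pos += len(seq)

    transcripts = {"pre-rRNA": unit_seq}
    pad = 20
    five_s_seq = _random_seq(rng, five_s_len + 2 * pad)
    transcripts["rrn-5S"] = five_s_seq
    features.append(FeatureInterval("rrn-5S", "5S", pad, pad + five_s_len))
    for i in range(n_decoys):
        transcripts[f"decoy-{i + 1}"] = _random_seq(rng, decoy_len)

    return RrnaReference(transcripts=transcripts, features=features)


# ---------------------------------------------------------------------------
# configuration


def _default_class_fractions() -> dict[str, float]:
    return {"sense_rRNA": 0.30, "risiRNA": 0.01, "other_mapped": 0.64, "unmapped": 0.05}


def _default_length_dist() -> dict[int, float]:
    return {
        18: 0.01, 19: 0.02, 20: 0.05, 21: 0.15, 22: 0.50, 23: 0.15,
        24: 0.05, 25: 0.03, 26: 0.02, 27: 0.01, 28: 0.005, 29: 0.0025, 30: 0.0025,
    }


def _default_u_runlen_dist() -> dict[int, float]:
    return {1: 0.7, 2: 0.2, 3: 0.1}


def _default_tail_class_probs() -> dict[str, float]:
    # a well-processed wild-type-like 3' end: mostly exact, some uridylation
    return {
        "no_tail": 0.90,
        "mono_A": 0.01, "mono_C": 0.005, "mono_G": 0.005, "mono_U": 0.02,
        "oligoU2": 0.02, "oligoU3": 0.012, "oligoU4": 0.008,
        "oligoU5": 0.006, "oligoU6": 0.004,
        "mixed": 0.01,
    }


def _default_end_trim_dist() -> dict[int, float]:
    return {0: 0.70, -1: 0.12, -2: 0.08, -3: 0.05, -4: 0.03, -5: 0.02}


@dataclass
class TailSimConfig:
    """Tail-seq library parameters."""

    rRNA_id: str = "26S"
    tail_class_probs: dict[str, float] = field(default_factory=_default_tail_class_probs)
    end_trim_dist: dict[int, float] = field(default_factory=_default_end_trim_dist)
    linker_id: str = "linker-1"


@dataclass
class SimConfig:
    """All knobs of the read simulator; the seed fixes the output bytes."""

    seed: int = 0
    n_reads: int = 10000
    class_fractions: dict[str, float] = field(default_factory=_default_class_fractions)
    length_dist: dict[int, float] = field(default_factory=_default_length_dist)
    firstnt_G_prob: float = 0.85
    untemplated_U_prob: float = 0.10
    U_runlen_dist: dict[int, float] = field(default_factory=_default_u_runlen_dist)
    seq_error_rate: float = 0.001
    allow_soft_tail: int = 4
    tailseq: TailSimConfig = field(default_factory=TailSimConfig)

    def __post_init__(self) -> None:
        for name, dist in (
            ("class_fractions", self.class_fractions),
            ("length_dist", self.length_dist),
            ("U_runlen_dist", self.U_runlen_dist),
            ("tail_class_probs", self.tailseq.tail_class_probs),
            ("end_trim_dist", self.tailseq.end_trim_dist),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} has negative probabilities")
        for name, p in (
            ("firstnt_G_prob", self.firstnt_G_prob),
            ("untemplated_U_prob", self.untemplated_U_prob),
            ("seq_error_rate", self.seq_error_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        tail = raw.pop("tailseq", None)
        cfg = cls(**raw)
        if tail:
            cfg.tailseq = TailSimConfig(**tail)
            cfg.__post_init__()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# helpers


def _categorical(rng: np.random.Generator, dist: dict, size: int) -> list:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=size, p=probs)
    return [keys[i] for i in idx]


def _inject_errors(seq: str, rng: np.random.Generator, rate: float) -> tuple[str, bool]:
    if rate <= 0.0:
        return seq, False
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq, False
    chars = list(seq)
    for i in hits:
        alternatives = [c for c in "ACGT" if c != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars), True


def _common_prefix_len(a: str, b: str) -> int:
    k = 0
    for x, y in zip(a, b):
        if x != y:
            break
        k += 1
    return k


def _feature_region(pos: int, end: int, feats: Sequence[FeatureInterval]) -> str:
    """Majority region of span [pos, end), ties to the 5'-most feature."""
    best, best_ovl = "", 0
    for f in feats:
        ovl = f.overlap(pos, end)
        if ovl > best_ovl:
            best, best_ovl = f.name, ovl
    return best


# ---------------------------------------------------------------------------
# small-RNA libraries


def simulate_smallrna(
    cfg: SimConfig, ref: RrnaReference, read_prefix: str = "sr"
) -> tuple[list[SmallRead], list[dict]]:
    """Simulate one small-RNA library; returns (reads, truth records).

    risiRNA reads are reverse-complement substrings of the pre-rRNA
    transcription unit (5' base biased to G by drawing positions whose
    antisense first base is G); sense-rRNA reads are sense substrings of
    mature rRNAs; decoy reads come from decoy transcripts; unmapped reads
    are random sequence. risiRNAs receive an untemplated 3' U run with
    probability ``untemplated_U_prob``. The 3' adaptor is appended to
    every read and substitution errors are injected last.

    Truth records hold the drawn class/tail and the *expected* pipeline
    outcome: U-run bases that coincide with the genomic continuation are
    absorbed as templated; an effective tail longer than the aligner's
    soft-tail allowance makes the read expectedly unmappable; trimmed
    inserts outside 18-30 nt are expectedly filtered.
    """
    rng = np.random.default_rng(cfg.seed)
    unit_tid = next(iter(ref.unit_transcript_ids))
    unit = ref.seq(unit_tid)
    unit_feats = ref.features_of(unit_tid)
    mature = [f for f in ref.features if f.name in ("18S", "5.8S", "26S", "5S")]
    mature_w = np.array([len(f) for f in mature], dtype=float)
    mature_w /= mature_w.sum()
    decoys = [t for t in ref.transcript_order if t not in ref.rrna_transcript_ids]
    g_positions = np.flatnonzero(np.frombuffer(unit.encode(), dtype=np.uint8) == ord("C"))

    n = cfg.n_reads
    classes = _categorical(rng, cfg.class_fractions, n)
    lengths = _categorical(rng, cfg.length_dist, n)
    g_flags = rng.random(n) < cfg.firstnt_G_prob
    u_flags = rng.random(n) < cfg.untemplated_U_prob
    runlens = _categorical(rng, cfg.U_runlen_dist, n)

    reads: list[SmallRead] = []
    truth: list[dict] = []
    for i in range(n):
        cls = classes[i]
        L = int(lengths[i])
        tail = ""
        tid = ""
        region = ""
        pos = -1
        expected_class = cls
        expected_tail = ""
        ambiguous = False

        if cls == "risiRNA":
            if g_flags[i] and g_positions.size:
                # antisense 5' base is the complement of the template 3' base:
                # pick a template position holding C so the read starts with G
                j = int(g_positions[rng.integers(0, g_positions.size)])
                pos = j - L + 1
                if pos < 0:
                    pos = int(rng.integers(0, len(unit) - L + 1))
            else:
                pos = int(rng.integers(0, len(unit) - L + 1))
            core = revcomp(unit[pos : pos + L])
            if u_flags[i]:
                tail = "T" * int(runlens[i])
            insert = core + tail
            tid = unit_tid
            region = _feature_region(pos, pos + L, unit_feats)
            # expected outcome under the greedy templated-extension rule
            continuation = revcomp(unit[max(0, pos - len(tail)) : pos])
            absorbed = _common_prefix_len(tail, continuation)
            expected_tail = tail[absorbed:]
            ambiguous = absorbed >= 1
            if not 18 <= len(insert) <= 30:
                expected_class = "filtered"
            elif len(expected_tail) > cfg.allow_soft_tail:
                expected_class = "unmapped"
        elif cls == "sense_rRNA":
            f = mature[int(rng.choice(len(mature), p=mature_w))]
            fl = min(L, len(f))
            pos = int(f.start + rng.integers(0, len(f) - fl + 1))
            insert = ref.seq(f.transcript_id)[pos : pos + fl]
            tid, region = f.transcript_id, f.name
        elif cls == "other_mapped":
            tid = decoys[int(rng.integers(0, len(decoys)))]
            seq = ref.seq(tid)
            pos = int(rng.integers(0, len(seq) - L + 1))
            insert = seq[pos : pos + L]
        else:  # unmapped
            insert = _random_seq(rng, L)

        read_seq, has_error = _inject_errors(insert + ADAPTOR_3P, rng, cfg.seq_error_rate)
        rid = f"{read_prefix}{i:07d}"
        reads.append(SmallRead(rid, read_seq))
        truth.append(
            {
                "read_id": rid,
                "true_class": cls,
                "transcript_id": tid,
                "position": pos,
                "region": region,
                "tail": tail,
                "expected_class": expected_class,
                "expected_tail": expected_tail,
                "expected_uridylated": bool(expected_tail)
                and set(expected_tail) == {"T"}
                and expected_class == "risiRNA",
                "ambiguous": ambiguous,
                "has_error": has_error,
            }
        )
    return reads, truth


# ---------------------------------------------------------------------------
# tail-seq libraries


def _draw_tail(kind: str, rng: np.random.Generator) -> str:
    if kind == "no_tail":
        return ""
    if kind.startswith("mono_"):
        return kind[-1].replace("U", "T")
    if kind.startswith("oligoU"):
        return "T" * int(kind[len("oligoU") :])
    # mixed: 2-4 bases that are neither empty, a single base, nor all U
    while True:
        k = int(rng.integers(2, 5))
        bases = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=k)])
        if classify_tail(bases) == "mixed":
            return bases


def simulate_tailseq(
    cfg: SimConfig,
    ref: RrnaReference,
    read_prefix: str = "ts",
    caller_max_mismatch: int = 2,
) -> tuple[list[SmallRead], list[dict]]:
    """Simulate one targeted tail-seq library; returns (reads, truth).

    Each read is the sense rRNA fragment from the embedded forward primer
    to the mature 3' end plus a drawn end trim (0..-5), followed by the
    drawn tail and the configured linker. The truth holds the drawn tail
    and the expected call under the caller's own boundary rule
    (:func:`risipipe.tailseq.split_templated_tail` with
    ``caller_max_mismatch``): tail bases absorbed as templated genomic
    read-through shift the expected boundary and shorten the expected
    tail, and such reads carry the ``ambiguous`` flag.
    """
    tcfg = cfg.tailseq
    feat = ref.feature(tcfg.rRNA_id)
    if feat is None:
        raise ValueError(f"reference lacks feature {tcfg.rRNA_id}")
    T = ref.seq(feat.transcript_id)
    E = feat.end
    primer = FORWARD_PRIMERS[tcfg.rRNA_id]
    p0 = T.find(primer, feat.start, feat.end)
    if p0 == -1:
        raise ValueError(f"forward primer for {tcfg.rRNA_id} not present in reference")
    linker = DEFAULT_LINKERS[tcfg.linker_id]

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reads
    trims = _categorical(rng, tcfg.end_trim_dist, n)
    kinds = _categorical(rng, tcfg.tail_class_probs, n)

    reads: list[SmallRead] = []
    truth: list[dict] = []
    for i in range(n):
        trim = int(trims[i])
        tail = _draw_tail(kinds[i], rng)
        frag = T[p0 : E + trim]
        read_seq, has_error = _inject_errors(frag + tail + linker, rng, cfg.seq_error_rate)

        # expected call: apply the caller's boundary rule to the clean insert
        b, _, expected_tail = split_templated_tail(frag + tail, T[p0:], caller_max_mismatch)
        boundary = p0 + b - E
        rid = f"{read_prefix}{i:07d}"
        reads.append(SmallRead(rid, read_seq))
        truth.append(
            {
                "read_id": rid,
                "rRNA_id": tcfg.rRNA_id,
                "linker_id": tcfg.linker_id,
                "end_trim": trim,
                "tail": tail,
                "tail_kind": kinds[i],
                "expected_end_offset": min(boundary, 0),
                "expected_templated_ext": max(0, boundary),
                "expected_tail": expected_tail,
                "expected_class": classify_tail(expected_tail),
                "ambiguous": expected_tail != tail,
                "has_error": has_error,
            }
        )
    return reads, truth


# ---------------------------------------------------------------------------
# file emission


def write_library(
    reads: Sequence[SmallRead], truth: Sequence[dict], out_dir: str | Path, name: str
) -> tuple[Path, Path]:
    """Write FASTQ + truth TSV for a simulated library; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fq = out / f"{name}.fastq"
    tt = out / f"{name}.truth.tsv"
    write_fastq(reads, fq)
    write_table(list(truth), tt)
    return fq, tt


def write_reference(ref: RrnaReference, out_dir: str | Path, name: str = "reference") -> tuple[Path, Path]:
    """Write a reference as FASTA + 4-column annotation TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fa = out / f"{name}.fa"
    an = out / f"{name}.annot.tsv"
    with open(fa, "w") as fh:
        for tid, seq in ref.transcripts.items():
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(an, "w") as fh:
        for f in ref.features:
            fh.write(f"{f.transcript_id}\t{f.start}\t{f.end}\t{f.name}\n")
    return fa, an
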