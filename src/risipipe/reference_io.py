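"""Reference sequences, annotations, read streaming and tabular I/O.

This module owns the coordinate and strand conventions for the whole
package:

* coordinates are 0-based half-open everywhere internally;
* reference transcripts are stored sense-strand in the DNA alphabet
  (RNA inputs are converted ``U`` -> ``T`` on read); "antisense" means a
  read matches the reverse complement of the stored sequence.

The reference model is a tiny transcript set: a pre-rRNA transcription
unit annotated with the ordered regions ETS5-18S-ITS1-5.8S-ITS2-26S-ETS3,
an independently transcribed 5S, and optional decoy transcripts that
stand in for the rest of the transcriptome.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, fields as dc_fields, is_dataclass, asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

#: Region names of the pre-rRNA transcription unit plus the 5S gene.
RRNA_FEATURE_NAMES = ("ETS5", "18S", "ITS1", "5.8S", "ITS2", "26S", "ETS3", "5S")

#: Mature rRNA species entering the normalization denominator.
MATURE_RRNAS = ("18S", "5.8S", "26S", "5S")

#: Length of downstream genomic context stored past each mature rRNA 3' end.
DOWNSTREAM_CONTEXT_LEN = 30

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceValidationError(ValueError):
    """Raised when a reference FASTA/annotation pair violates an invariant."""


class TruncatedFastqError(ValueError):
    """Raised when a FASTQ file ends partway through a record."""


@dataclass(frozen=True)
class FeatureInterval:
    """A named interval on a transcript, 0-based half-open."""

    transcript_id: str
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ReferenceValidationError(
                f"feature {self.name} on {self.transcript_id}: "
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class SmallRead:
    """A single sequencing read (DNA alphabet, optional quality string)."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"read {self.id}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class RrnaReference:
    """Validated transcript set with rRNA feature annotation.

    transcripts preserve insertion order (the FASTA order), which gives
    deterministic tie-breaks downstream.
    """

    transcripts: dict[str, str]
    features: list[FeatureInterval]
    downstream_context: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()
        # canonical feature order: transcript (FASTA order), then start
        order = {tid: i for i, tid in enumerate(self.transcripts)}
        self.features = sorted(self.features, key=lambda f: (order[f.transcript_id], f.start))
        if not self.downstream_context:
            self.downstream_context = self._extract_downstream_context()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        for tid, seq in self.transcripts.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ReferenceValidationError(
                    f"transcript {tid}: non-ACGTN characters {sorted(bad)}"
                )
        seen_mature: set[str] = set()
        by_tid: dict[str, list[FeatureInterval]] = {}
        for f in self.features:
            if f.transcript_id not in self.transcripts:
                raise ReferenceValidationError(
                    f"feature {f.name}: unknown transcript {f.transcript_id}"
                )
            tlen = len(self.transcripts[f.transcript_id])
            if f.end > tlen:
                raise ReferenceValidationError(
                    f"feature {f.name} on {f.transcript_id}: end {f.end} "
                    f"exceeds transcript length {tlen}"
                )
            if f.name in MATURE_RRNAS:
                if f.name in seen_mature:
                    raise ReferenceValidationError(f"mature rRNA {f.name} annotated twice")
                seen_mature.add(f.name)
            by_tid.setdefault(f.transcript_id, []).append(f)
        for tid, feats in by_tid.items():
            feats = sorted(feats, key=lambda f: f.start)
            for a, b in zip(feats, feats[1:]):
                if b.start < a.end:
                    raise ReferenceValidationError(
                        f"features {a.name} and {b.name} overlap on {tid}"
                    )

    def _extract_downstream_context(self) -> dict[str, str]:
        ctx: dict[str, str] = {}
        for f in self.features:
            if f.name in MATURE_RRNAS:
                seq = self.transcripts[f.transcript_id]
                tail = seq[f.end : f.end + DOWNSTREAM_CONTEXT_LEN]
                if tail:
                    ctx[f.name] = tail
        return ctx

    # -- lookups ---------------------------------------------------------

    @property
    def transcript_order(self) -> list[str]:
        return list(self.transcripts)

    def seq(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id]

    def features_of(self, transcript_id: str) -> list[FeatureInterval]:
        return [f for f in self.features if f.transcript_id == transcript_id]

    def feature(self, name: str) -> FeatureInterval | None:
        """The unique feature with this name (mature rRNAs), else None."""
        for f in self.features:
            if f.name == name:
                return f
        return None

    @property
    def rrna_transcript_ids(self) -> set[str]:
        """Transcripts carrying any rRNA feature (unit and 5S)."""
        return {f.transcript_id for f in self.features}

    @property
    def unit_transcript_ids(self) -> set[str]:
        """Transcripts carrying pre-rRNA transcription-unit features."""
        return {f.transcript_id for f in self.features if f.name != "5S"}

    @property
    def five_s_transcript_ids(self) -> set[str]:
        return {f.transcript_id for f in self.features if f.name == "5S"} - self.unit_transcript_ids

    def has_downstream_context(self, rrna_name: str) -> bool:
        return bool(self.downstream_context.get(rrna_name))


# ---------------------------------------------------------------------------
# loading


def _clean_seq(raw: str, record_id: str) -> str:
    seq = str(raw).upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ReferenceValidationError(
            f"transcript {record_id}: non-ACGTN characters {sorted(bad)}"
        )
    return seq


def load_reference(fasta_path: str | Path, annotation_path: str | Path) -> RrnaReference:
    """Load and validate a reference FASTA plus 4-column TSV annotation.

    The annotation columns are tab-separated
    ``transcript_id  start  end  name`` with 0-based half-open coordinates.
    Lines starting with ``#`` are ignored. Validation is order-independent
    with respect to annotation row order.
    """
    transcripts: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in transcripts:
            raise ReferenceValidationError(f"duplicate transcript id {rec.id}")
        transcripts[rec.id] = _clean_seq(rec.seq, rec.id)

    df = pd.read_csv(
        annotation_path,
        sep="\t",
        comment="#",
        header=None,
        names=["transcript_id", "start", "end", "name"],
        dtype={"transcript_id": str, "start": int, "end": int, "name": str},
    )
    features = [
        FeatureInterval(r.transcript_id, r.name, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]
    return RrnaReference(transcripts=transcripts, features=features)


def load_annotation_gff3(path: str | Path) -> list[FeatureInterval]:
    """Convenience GFF3 importer (feature types ``rRNA`` and ``region``).

    GFF3 is 1-based inclusive; intervals are converted to the internal
    0-based half-open convention. The feature name is taken from the
    ``Name`` attribute, falling back to ``ID``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[FeatureInterval] = []
    for f in db.all_features():
        if f.featuretype not in ("rRNA", "region"):
            continue
        name = f.attributes.get("Name", f.attributes.get("ID", [f.id]))[0]
        out.append(FeatureInterval(f.seqid, name, f.start - 1, f.end))
    return out


# ---------------------------------------------------------------------------
# read streaming


def _open_text(path: str | Path):
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, "rt")
    return open(p, "rt")


def stream_fastq(path: str | Path) -> Iterator[SmallRead]:
    """Yield reads from a FASTQ file (plain or gzip) in file order.

    Raises :class:`TruncatedFastqError` naming the record index if the
    file ends partway through a record.
    """
    n = 0
    with _open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise TruncatedFastqError(
                    f"{path}: truncated or malformed FASTQ at record {n + 1}: {exc}"
                ) from exc
            n += 1
            yield SmallRead(title.split()[0], seq.upper().replace("U", "T"), qual)


def write_fastq(reads: Iterable[SmallRead], path: str | Path) -> int:
    """Write reads as plain FASTQ (byte-deterministic). Returns read count."""
    n = 0
    p = Path(path)
    opener = gzip.open if p.suffix == ".gz" else open
    with opener(p, "wt") as out:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            out.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# tabular output


def _row_dict(row) -> dict:
    if is_dataclass(row):
        return asdict(row)
    return dict(row)


def write_table(rows: Sequence, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records as a TSV with header.

    Column order is deterministic: the explicit ``columns`` argument if
    given, else the field order of the first record. An empty ``rows``
    with ``columns`` yields a header-only file.
    """
    dicts = [_row_dict(r) for r in rows]
    if columns is None:
        if dicts:
            columns = list(dicts[0].keys())
        else:
            columns = []
    df = pd.DataFrame(dicts, columns=list(columns))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> list[dict]:
    """Read a TSV written by :func:`write_table` back to a list of dicts."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return []
    return df.to_dict(orient="records")
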