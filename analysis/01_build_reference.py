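#!/usr/bin/env python
"""Build the toy rRNA reference the whole analysis runs against.

Writes a random-sequence pre-rRNA transcription unit with the ordered
regions ETS5-18S-ITS1-5.8S-ITS2-26S-ETS3, a separate 5S transcript and
two decoy mRNAs (FASTA + 4-column annotation) under results/reference/,
and prints the feature table and the downstream context available for
tail calling.
"""

from common import RESULTS, get_reference


def main() -> None:
    ref = get_reference()
    print(f"reference written under {RESULTS / 'reference'}")
    print(f"\ntranscripts ({len(ref.transcripts)}):")
    for tid, seq in ref.transcripts.items():
        print(f"  {tid:10s} {len(seq):5d} nt")
    print("\nfeatures (0-based half-open):")
    for f in ref.features:
        print(f"  {f.transcript_id:10s} {f.name:5s} [{f.start:5d}, {f.end:5d})")
    print("\ndownstream context for tail calling:")
    for name, ctx in sorted(ref.downstream_context.items()):
        print(f"  {name:5s} {ctx}")


if __name__ == "__main__":
    main()
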