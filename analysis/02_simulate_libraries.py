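#!/usr/bin/env python
"""Simulate every library of the study with per-read ground truth.

Small-RNA libraries: five baseline/mutant pairs whose true risiRNA
enrichments mirror the study's comparisons (total RNA 4.7x; NRDE-3,
HRDE-1, WAGO-1 IPs 17x / 9.9x / 1.6x; NRDE-3 IP in the enhanced-RNAi
background 164x). Tail-seq libraries: three replicates per genotype and
temperature for 26S and 5.8S. FASTQ + truth tables land under
scratch/sim/ (regenerated deterministically when absent).
"""

from common import SCRATCH, get_reference, simulate_smallrna_libraries, simulate_tailseq_libraries


def main() -> None:
    ref = get_reference()
    sr = simulate_smallrna_libraries(ref, force=True)
    print(f"small-RNA libraries under {SCRATCH / 'smallrna'}:")
    for name, pair in sr.items():
        print(f"  {name}: {pair['mutant'].name}, {pair['baseline'].name}")
    ts = simulate_tailseq_libraries(ref, force=True)
    print(f"\ntail-seq libraries under {SCRATCH / 'tailseq'}: {len(ts)} files")


if __name__ == "__main__":
    main()
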