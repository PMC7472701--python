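"""Shared configuration for the analysis drivers.

Desk-scale library sizes (20k small-RNA reads, 2k tail-seq reads per
replicate) keep every driver under a minute; the acceptance script runs
the same computations at 100k reads per library.
"""

from pathlib import Path

from risipipe import study
from risipipe.reference_io import RrnaReference, load_reference
from risipipe.synthetic import make_reference, simulate_smallrna, simulate_tailseq, write_library, write_reference

STUDY_SEED = 2020
N_SMALLRNA = 20_000
N_TAILSEQ = 2_000
SEQ_ERROR = 0.001  # Illumina-like substitution rate

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "sim"

TAIL_CONDITIONS = ("wildtype_20C", "pup_mutant_20C", "wildtype_coldshock",
                   "pup_mutant_coldshock", "exonuclease_mutant_20C")
TAIL_GENES = ("26S", "5.8S")
N_REPLICATES = 3


def get_reference() -> RrnaReference:
    """The study reference, loading the written copy when present."""
    fa = RESULTS / "reference" / "reference.fa"
    an = RESULTS / "reference" / "reference.annot.tsv"
    if fa.exists() and an.exists():
        return load_reference(fa, an)
    ref = make_reference(seed=STUDY_SEED)
    write_reference(ref, RESULTS / "reference")
    return ref


def smallrna_library_paths() -> dict[str, dict[str, Path]]:
    return {
        name: {
            "mutant": SCRATCH / "smallrna" / f"{name}_mutant.fastq",
            "baseline": SCRATCH / "smallrna" / f"{name}_baseline.fastq",
        }
        for name in study.ENRICHMENT_SCENARIOS
    }


def simulate_smallrna_libraries(ref: RrnaReference, force: bool = False) -> dict[str, dict[str, Path]]:
    """Simulate (or reuse) the five paired small-RNA libraries."""
    paths = smallrna_library_paths()
    for i, (name, ratio) in enumerate(study.ENRICHMENT_SCENARIOS.items()):
        if not force and all(p.exists() for p in paths[name].values()):
            continue
        mut_cfg, base_cfg = study.paired_configs(
            ratio, N_SMALLRNA,
            seed_a=STUDY_SEED + 100 + 2 * i,
            seed_b=STUDY_SEED + 101 + 2 * i,
            baseline_risirna=study.BASELINE_RISIRNA_FRACTION[name],
            seq_error_rate=SEQ_ERROR,
        )
        for label, cfg in (("mutant", mut_cfg), ("baseline", base_cfg)):
            reads, truth = simulate_smallrna(cfg, ref, read_prefix=f"{name}_{label}_")
            write_library(reads, truth, SCRATCH / "smallrna", f"{name}_{label}")
    return paths


def tailseq_library_paths() -> dict[tuple[str, str, int], Path]:
    return {
        (gene, cond, rep): SCRATCH / "tailseq" / f"{gene}_{cond}_rep{rep}.fastq"
        for gene in TAIL_GENES
        for cond in TAIL_CONDITIONS
        for rep in range(1, N_REPLICATES + 1)
    }


def simulate_tailseq_libraries(ref: RrnaReference, force: bool = False) -> dict[tuple[str, str, int], Path]:
    """Simulate (or reuse) tail-seq replicates for every gene x condition."""
    paths = tailseq_library_paths()
    offset = 0
    for (gene, cond, rep), path in paths.items():
        offset += 1
        if not force and path.exists():
            continue
        cfg = study.tailseq_config(
            cond, gene, seed=STUDY_SEED + 500 + offset, n_reads=N_TAILSEQ,
            seq_error_rate=SEQ_ERROR,
        )
        reads, truth = simulate_tailseq(cfg, ref, read_prefix=f"{gene}_{cond}_r{rep}_")
        write_library(reads, truth, SCRATCH / "tailseq", path.stem)
    return paths
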