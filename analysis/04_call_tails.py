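#!/usr/bin/env python
"""Call 26S/5.8S 3' tails in every tail-seq library and compare conditions.

Demultiplexes the barcoded linker, verifies the gene-specific forward
primer, splits each insert into templated sequence and untemplated tail,
and aggregates per-replicate tail-class fractions (mean +/- SD, n = 3).
Conditions are compared with a two-tailed Student's t-test on the
oligo-U fraction. Tables and figures go to results/tailseq/.
"""

from common import (
    N_REPLICATES,
    RESULTS,
    TAIL_CONDITIONS,
    TAIL_GENES,
    get_reference,
    simulate_tailseq_libraries,
)
from risipipe.reference_io import stream_fastq, write_table
from risipipe.report import render_reports
from risipipe.stats import significance_stars
from risipipe.tailseq import compare_conditions, run_tailseq, summarize_tails

COMPARISONS = [
    ("pup_mutant_20C", "wildtype_20C"),
    ("wildtype_coldshock", "wildtype_20C"),
    ("pup_mutant_coldshock", "wildtype_coldshock"),
    ("exonuclease_mutant_20C", "wildtype_20C"),
]


def main() -> None:
    ref = get_reference()
    paths = simulate_tailseq_libraries(ref)
    out = RESULTS / "tailseq"

    summaries = {}
    for gene in TAIL_GENES:
        for cond in TAIL_CONDITIONS:
            reps = {}
            for rep in range(1, N_REPLICATES + 1):
                reads = stream_fastq(paths[(gene, cond, rep)])
                calls, log = run_tailseq(reads, ref, rRNA_id=gene)
                reps[f"rep{rep}"] = calls
            summaries[(gene, cond)] = summarize_tails(reps, sample_id=f"{gene}_{cond}", rRNA_id=gene)

    comparison_rows = []
    for gene in TAIL_GENES:
        print(f"\n{gene} oligo-U fraction (mean over {N_REPLICATES} replicates):")
        for cond in TAIL_CONDITIONS:
            s = summaries[(gene, cond)]
            sd = s.class_sd.get("oligoU")
            print(f"  {cond:<24} {s.class_mean['oligoU']:.4f} +/- {sd if sd is None else round(sd, 4)}")
        for a, b in COMPARISONS:
            diff, p = compare_conditions(summaries[(gene, a)], summaries[(gene, b)], "oligoU")
            stars = significance_stars(p)
            comparison_rows.append(
                {"rRNA_id": gene, "condition_a": a, "condition_b": b,
                 "class": "oligoU", "difference": round(diff, 4),
                 "p_value": p, "significance": stars}
            )
            print(f"  {a} vs {b}: diff={diff:+.4f}, p={p:.2e} {stars}")

    write_table(comparison_rows, out / "comparisons.tsv")
    render_reports(out, tail_summaries=[summaries[k] for k in sorted(summaries)],
                   comparisons=comparison_rows)
    print(f"\ntables and figures under {out}")


if __name__ == "__main__":
    main()
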