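"""Deterministic report tables and figures.

Every number that appears in a figure is also written as a TSV, so no
value is plot-only. Tables are byte-deterministic for identical inputs;
figures are rendered with the Agg backend.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .reference_io import RRNA_FEATURE_NAMES, write_table
from .smallrna import CountSummary
from .tailseq import TAIL_CLASSES, TailSummary

_COUNT_COLS = [
    "sample_id",
    "total_clean",
    "total_mapped",
    "sense_rRNA",
    "sense_spacer",
    "risiRNA",
    "risiRNA_5S",
    "other_mapped",
    "unmapped",
    "norm_denominator",
    "zero_denominator",
]


def counts_rows(summaries: Sequence[CountSummary]) -> list[dict]:
    return [{c: getattr(s, c) for c in _COUNT_COLS} for s in summaries]


def region_rows(summaries: Sequence[CountSummary]) -> list[dict]:
    rows = []
    for s in summaries:
        for region in RRNA_FEATURE_NAMES:
            if region == "5S":
                continue
            rows.append(
                {"sample_id": s.sample_id, "region": region, "risiRNA_count": s.per_region.get(region, 0)}
            )
    return rows


def profile_rows(profiles: Mapping[str, "object"]) -> list[dict]:
    rows = []
    for sample_id in profiles:
        mat = profiles[sample_id]
        for length, row in mat.iterrows():
            rows.append(
                {"sample_id": sample_id, "length": int(length), **{c: int(row[c]) for c in mat.columns}}
            )
    return rows


def tail_rows(summaries: Sequence[TailSummary]) -> list[dict]:
    rows = []
    for s in summaries:
        n_reps = len(s.replicate_ids)
        for cls in TAIL_CLASSES:
            counts = [s.per_replicate_counts[r][cls] for r in s.replicate_ids]
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "rRNA_id": s.rRNA_id,
                    "tail_class": cls,
                    "n_replicates": n_reps,
                    "total_count": sum(counts),
                    "mean_fraction": s.class_mean.get(cls, float("nan")),
                    "sd_fraction": s.class_sd.get(cls) if s.class_sd.get(cls) is not None else "",
                }
            )
    return rows


def oligou_rows(summaries: Sequence[TailSummary]) -> list[dict]:
    keys = ["1", "2", "3", "4", "5", "6+"]
    return [
        {"sample_id": s.sample_id, "rRNA_id": s.rRNA_id, "u_run_length": k,
         "count": s.oligoU_by_len.get(k, 0)}
        for s in summaries
        for k in keys
    ]


def render_reports(
    out_dir: str | Path,
    count_summaries: Sequence[CountSummary] | None = None,
    profiles: Mapping[str, "object"] | None = None,
    tail_summaries: Sequence[TailSummary] | None = None,
    comparisons: Sequence[dict] | None = None,
) -> list[Path]:
    """Write all tables and figures for the given summaries.

    Returns the list of files written. Missing inputs are simply
    skipped; an empty comparison list yields tables only.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _table(rows: list[dict], name: str, columns=None) -> None:
        path = out / name
        write_table(rows, path, columns=columns)
        written.append(path)

    if count_summaries:
        _table(counts_rows(count_summaries), "counts.tsv")
        rrows = region_rows(count_summaries)
        _table(rrows, "per_region.tsv")
        fig, ax = plt.subplots(figsize=(7, 3.5))
        samples = sorted({r["sample_id"] for r in rrows})
        regions = [n for n in RRNA_FEATURE_NAMES if n != "5S"]
        width = 0.8 / max(1, len(samples))
        for i, sample in enumerate(samples):
            vals = [
                next(r["risiRNA_count"] for r in rrows if r["sample_id"] == sample and r["region"] == reg)
                for reg in regions
            ]
            ax.bar([x + i * width for x in range(len(regions))], vals, width, label=sample)
        ax.set_xticks([x + 0.4 for x in range(len(regions))])
        ax.set_xticklabels(regions)
        ax.set_ylabel("risiRNA reads")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "per_region.png", dpi=120)
        plt.close(fig)
        written.append(out / "per_region.png")

    if profiles:
        _table(profile_rows(profiles), "size_firstnt.tsv")
        for sample_id in profiles:
            mat = profiles[sample_id]
            fig, ax = plt.subplots(figsize=(6, 3))
            bottom = None
            for base in mat.columns:
                vals = mat[base].to_numpy()
                ax.bar(mat.index, vals, bottom=bottom, label=base)
                bottom = vals if bottom is None else bottom + vals
            ax.set_xlabel("read length (nt)")
            ax.set_ylabel("reads")
            ax.set_title(sample_id, fontsize=8)
            ax.legend(title="5' nt", fontsize=7)
            fig.tight_layout()
            safe = sample_id.replace("/", "_")
            fig.savefig(out / f"size_firstnt_{safe}.png", dpi=120)
            plt.close(fig)
            written.append(out / f"size_firstnt_{safe}.png")

    if tail_summaries:
        _table(tail_rows(tail_summaries), "tail_classes.tsv")
        _table(oligou_rows(tail_summaries), "oligoU_lengths.tsv")
        fig, ax = plt.subplots(figsize=(7, 3.5))
        width = 0.8 / max(1, len(tail_summaries))
        for i, s in enumerate(tail_summaries):
            means = [s.class_mean.get(c, 0.0) for c in TAIL_CLASSES]
            sds = [s.class_sd.get(c) or 0.0 for c in TAIL_CLASSES]
            ax.bar(
                [x + i * width for x in range(len(TAIL_CLASSES))],
                means,
                width,
                yerr=sds,
                capsize=2,
                label=s.sample_id,
            )
        ax.set_xticks([x + 0.4 for x in range(len(TAIL_CLASSES))])
        ax.set_xticklabels(TAIL_CLASSES, rotation=30, ha="right", fontsize=7)
        ax.set_ylabel("fraction of reads (mean +/- SD)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "tail_classes.png", dpi=120)
        plt.close(fig)
        written.append(out / "tail_classes.png")

    if comparisons is not None and len(comparisons) > 0:
        _table(list(comparisons), "comparisons.tsv")

    return written
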