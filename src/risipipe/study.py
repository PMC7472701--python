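"""Study-condition presets: paired libraries and tail-seq genotypes.

The comparisons the pipeline is built to reproduce are pairs of
small-RNA libraries (a uridylation-competent baseline against a
uridylation-deficient mutant, total RNA or Argonaute IP) with a known
true risiRNA enrichment, and tail-seq conditions whose 26S/5.8S 3' ends
differ in oligo-U load. The presets below encode those conditions for
the synthetic generator; the mutant risiRNA fraction is solved so that
the pair's true per-million ratio equals the requested enrichment
exactly.
"""

from __future__ import annotations

from dataclasses import replace

from .synthetic import SimConfig, TailSimConfig

#: Enrichment of risiRNA in the uridylation-deficient mutant over its
#: control, per library type (total small RNA and Argonaute IPs; the
#: last is the IP in an enhanced-RNAi background where the baseline
#: risiRNA pool is nearly absent).
ENRICHMENT_SCENARIOS: dict[str, float] = {
    "total_smallrna": 4.7,
    "nrde3_ip": 17.0,
    "hrde1_ip": 9.9,
    "wago1_ip": 1.6,
    "nrde3_ip_eri1": 164.0,
}

#: Baseline risiRNA fraction per scenario. ~1% of clean reads for
#: ordinary libraries; the enhanced-RNAi background starts much lower
#: (which is why its enrichment can reach two orders of magnitude).
BASELINE_RISIRNA_FRACTION: dict[str, float] = {
    "total_smallrna": 0.01,
    "nrde3_ip": 0.01,
    "hrde1_ip": 0.01,
    "wago1_ip": 0.01,
    "nrde3_ip_eri1": 0.0035,
}


def paired_configs(
    true_ratio: float,
    n_reads: int,
    seed_a: int,
    seed_b: int,
    baseline_risirna: float = 0.01,
    sense_fraction: float = 0.30,
    unmapped_fraction: float = 0.05,
    seq_error_rate: float = 0.0,
    mutant_u_prob: float = 0.02,
    baseline_u_prob: float = 0.30,
) -> tuple[SimConfig, SimConfig]:
    """(mutant, baseline) SimConfigs with true risiRNA enrichment ``true_ratio``.

    Both libraries share the sense-rRNA and unmapped fractions, so the
    expected per-million ratio reduces to the risiRNA fraction ratio and
    the mutant fraction is simply ``true_ratio * baseline_risirna``. The
    mutant also loses most untemplated 3' U marks on its risiRNAs (the
    uridylation writer is absent), controlled by the two U probabilities.
    """
    f_mut = true_ratio * baseline_risirna
    budget = 1.0 - sense_fraction - unmapped_fraction
    if f_mut >= budget:
        raise ValueError(
            f"true ratio {true_ratio} with baseline fraction {baseline_risirna} "
            f"needs mutant risiRNA fraction {f_mut:.3f} >= available {budget:.3f}"
        )

    def _cfg(seed: int, f_risi: float, u_prob: float) -> SimConfig:
        return SimConfig(
            seed=seed,
            n_reads=n_reads,
            class_fractions={
                "sense_rRNA": sense_fraction,
                "risiRNA": f_risi,
                "other_mapped": budget - f_risi,
                "unmapped": unmapped_fraction,
            },
            untemplated_U_prob=u_prob,
            seq_error_rate=seq_error_rate,
        )

    return _cfg(seed_a, f_mut, mutant_u_prob), _cfg(seed_b, baseline_risirna, baseline_u_prob)


def _tail_probs(mono_u: float, oligo_u_total: float, rRNA_id: str) -> dict[str, float]:
    """Tail-class distribution with the requested uridylation load.

    The oligo-U run-length profile differs between the two genes: 26S
    ends receive mostly 3-6 U runs, 5.8S ends mostly 1-3.
    """
    if rRNA_id == "26S":
        oligo_w = {2: 0.10, 3: 0.30, 4: 0.30, 5: 0.20, 6: 0.10}
    else:
        oligo_w = {2: 0.45, 3: 0.30, 4: 0.15, 5: 0.06, 6: 0.04}
    other = {"mono_A": 0.010, "mono_C": 0.005, "mono_G": 0.005, "mixed": 0.010}
    probs = {"no_tail": 1.0 - mono_u - oligo_u_total - sum(other.values())}
    probs.update(other)
    probs["mono_U"] = mono_u
    for k, w in oligo_w.items():
        probs[f"oligoU{k}"] = oligo_u_total * w
    return probs


#: Tail-seq conditions: (mono-U fraction, total oligo-U fraction) per
#: genotype/treatment. The uridylation-writer mutant is depleted for
#: oligo-U; cold shock strongly induces it (and mono-U on 5.8S); the
#: exonuclease mutant accumulates it because degradation of the
#: uridylated species is lost.
TAILSEQ_CONDITIONS: dict[str, dict[str, tuple[float, float]]] = {
    "26S": {
        "wildtype_20C": (0.020, 0.050),
        "pup_mutant_20C": (0.020, 0.015),
        "wildtype_coldshock": (0.020, 0.150),
        "pup_mutant_coldshock": (0.020, 0.020),
        "exonuclease_mutant_20C": (0.020, 0.120),
    },
    "5.8S": {
        "wildtype_20C": (0.020, 0.040),
        "pup_mutant_20C": (0.015, 0.012),
        "wildtype_coldshock": (0.080, 0.120),
        "pup_mutant_coldshock": (0.020, 0.015),
        "exonuclease_mutant_20C": (0.060, 0.100),
    },
}


def tailseq_config(
    condition: str,
    rRNA_id: str,
    seed: int,
    n_reads: int = 3000,
    linker_id: str = "linker-1",
    seq_error_rate: float = 0.0,
) -> SimConfig:
    """SimConfig for one tail-seq replicate of a named condition."""
    mono_u, oligo_u = TAILSEQ_CONDITIONS[rRNA_id][condition]
    return SimConfig(
        seed=seed,
        n_reads=n_reads,
        seq_error_rate=seq_error_rate,
        tailseq=TailSimConfig(
            rRNA_id=rRNA_id,
            tail_class_probs=_tail_probs(mono_u, oligo_u, rRNA_id),
            linker_id=linker_id,
        ),
    )
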