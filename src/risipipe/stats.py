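"""Replicate statistics and qPCR quantification.

mean +/- sample SD over biological replicates, the two-tailed Student's
t-test used for condition comparisons, and the comparative threshold
cycle (delta-delta-CT) method for relative qPCR quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ReplicateVector:
    """Measurements (counts or fractions) for one condition."""

    condition: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError(f"{self.condition}: need at least one replicate")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CtRecord:
    """Threshold cycles for a target gene and the internal-control gene."""

    sample_id: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, ct in (("target", self.ct_target), ("reference", self.ct_reference)):
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"{self.sample_id}: {name} Ct must be finite and > 0, got {ct}")


def mean_sd(values: Sequence[float]) -> tuple[float, float | None]:
    """Arithmetic mean and sample SD (n-1 denominator; None when n = 1)."""
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("empty replicate vector")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
    return mean, sd


def ttest_two_tailed(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> float:
    """Two-sample two-tailed Student's t-test p-value.

    Equal-variance by default (``equal_var=False`` gives Welch's test).
    The zero-variance degenerate case is handled as the limit: p = 1
    when both samples are constant and equal, p = 0 when constant and
    different.
    """
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicates per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.pvalue)


def delta_delta_ct(sample: CtRecord, control: CtRecord) -> float:
    """Relative expression 2**(-ddCT).

    ddCT = (Ct_target - Ct_reference)_sample - (Ct_target - Ct_reference)_control.
    """
    ddct = (sample.ct_target - sample.ct_reference) - (
        control.ct_target - control.ct_reference
    )
    return 2.0 ** (-ddct)


def significance_stars(p: float | None) -> str:
    """Star annotation convention: ** p<0.01, * p<0.05, ns otherwise."""
    if p is None:
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
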