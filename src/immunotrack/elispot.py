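"""ELISPOT response magnitudes and positivity calling, plus the ex-vivo
intracellular-staining (ICS) background rule.

An assay is a small set of replicate wells: antigen-stimulated (IDO or
PD-L1 peptide) and DMSO control. The response magnitude is the difference
of replicate means. Positivity follows a distribution-free resampling (DFR)
permutation test on the replicate labels: the one-sided mean-difference
statistic is recomputed over every partition of the pooled wells into groups
of the original sizes (exhaustively when feasible, Monte-Carlo otherwise).
The ``2x`` variant doubles the control counts first, testing
antigen > 2x control. Assays run in duplicate can never reach p <= 0.05
exhaustively (only C(4,2)=6 partitions), so a duplicate rule applies:
antigen mean at least twice the control mean is called a response (DR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .errors import UnavailableMetricError, ValidationError
from .io import TIMEPOINTS

__all__ = [
    "ElispotAssay",
    "ResponseCall",
    "response_magnitude",
    "dfr_test",
    "classify_response",
    "best_on_treatment",
    "paired_cohort_test",
    "ics_response",
]

#: Spot count recorded for wells too numerous to count (TNTC).
TNTC_CEILING = 500


@dataclass
class ElispotAssay:
    """Replicate spot counts for one subject/timepoint/antigen.

    TNTC wells should be mapped to :data:`TNTC_CEILING` before construction;
    ``metadata['tntc_wells']`` records how many were capped.
    """

    subject_id: str
    timepoint: str
    antigen: str
    antigen_wells: list[int]
    control_wells: list[int]
    cells_per_well: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, wells in (("antigen", self.antigen_wells), ("control", self.control_wells)):
            if len(wells) < 2:
                raise ValidationError(
                    f"{self.subject_id}/{self.timepoint}: need >=2 {name} replicates"
                )
            if any(w < 0 or not np.isfinite(w) for w in wells):
                raise ValidationError(f"{name} wells must be finite nonnegative counts")


@dataclass(frozen=True)
class ResponseCall:
    """Outcome of positivity calling for one assay.

    ``call`` is 'significant' (DFR p <= threshold), 'DR' (not significant
    but antigen mean >= 2x control mean), or 'NS'.
    """

    subject_id: str
    timepoint: str
    antigen: str
    magnitude: float
    p_value: float | None
    call: str


def response_magnitude(assay: ElispotAssay) -> float:
    """mean(antigen wells) - mean(control wells); negative values kept."""
    return float(np.mean(assay.antigen_wells) - np.mean(assay.control_wells))


def dfr_test(
    antigen_wells: list[int],
    control_wells: list[int],
    variant: str = "eq",
    max_exhaustive: int = 20_000,
    n_resamples: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Distribution-free resampling p-value for antigen > control.

    Exact permutation test with statistic mean(antigen) - mean(control) over
    all C(na+nc, na) partitions of the pooled wells into groups of the
    original sizes; the p-value is the fraction of partitions (including the
    observed one) whose statistic is at least the observed. For ``variant
    '2x'`` control counts are doubled before pooling, testing whether the
    antigen wells exceed twice the control. Falls back to seeded Monte-Carlo
    with ``n_resamples`` draws when the partition count exceeds
    ``max_exhaustive``.
    """
    if variant not in ("eq", "2x"):
        raise ValidationError(f"unknown DFR variant {variant!r}")
    a = np.asarray(antigen_wells, dtype=float)
    c = np.asarray(control_wells, dtype=float)
    if a.size < 2 or c.size < 2:
        raise ValidationError("need >=2 replicates per condition")
    if variant == "2x":
        c = 2.0 * c
    pooled = np.concatenate([a, c])
    na, n = a.size, a.size + c.size
    observed = a.mean() - c.mean()
    tol = 1e-12
    if comb(n, na) <= max_exhaustive:
        hits = total = 0
        for idx in combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            stat = pooled[mask].mean() - pooled[~mask].mean()
            hits += stat >= observed - tol
            total += 1
        return hits / total
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 1  # the observed partition counts itself
    for _ in range(n_resamples):
        perm = rng.permutation(pooled)
        stat = perm[:na].mean() - perm[na:].mean()
        hits += stat >= observed - tol
    return hits / (n_resamples + 1)


def classify_response(
    assay: ElispotAssay,
    variant: str = "eq",
    p_threshold: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> ResponseCall:
    """Call an assay significant / DR / NS.

    Significant when the DFR p-value passes ``p_threshold`` and the
    magnitude is positive; otherwise DR when mean antigen >= 2x mean
    control; otherwise NS. Negative-magnitude assays are NS regardless of p.
    """
    magnitude = response_magnitude(assay)
    p = dfr_test(assay.antigen_wells, assay.control_wells, variant=variant, seed=seed)
    mean_a = float(np.mean(assay.antigen_wells))
    mean_c = float(np.mean(assay.control_wells))
    if p <= p_threshold and magnitude > 0:
        call = "significant"
    elif mean_a >= 2.0 * mean_c and magnitude > 0:
        call = "DR"
    else:
        call = "NS"
    return ResponseCall(
        subject_id=assay.subject_id,
        timepoint=assay.timepoint,
        antigen=assay.antigen,
        magnitude=magnitude,
        p_value=p,
        call=call,
    )


def best_on_treatment(calls: list[ResponseCall]) -> ResponseCall:
    """The on-treatment call with the largest magnitude.

    Ties go to the earliest timepoint in the study ordering.
    """
    if not calls:
        raise UnavailableMetricError("no on-treatment calls")
    order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    return max(calls, key=lambda c: (c.magnitude, -order.get(c.timepoint, len(order))))


def paired_cohort_test(
    baseline_magnitudes: list[float], best_magnitudes: list[float]
) -> float:
    """Two-sided Wilcoxon matched-pairs signed-rank p-value.

    Compares subjects' baseline response magnitudes with their best
    on-treatment magnitudes; requires at least 5 pairs.
    """
    x = np.asarray(baseline_magnitudes, dtype=float)
    y = np.asarray(best_magnitudes, dtype=float)
    if x.size != y.size:
        raise ValidationError("paired samples must have equal length")
    if x.size < 5:
        raise ValidationError("at least 5 pairs required")
    if np.all(x == y):
        return 1.0
    return float(stats.wilcoxon(x, y, alternative="two-sided").pvalue)


def ics_response(
    stim_percent: float, unstim_percent: float, threshold: float = 0.2
) -> tuple[float, bool]:
    """Background-subtracted ICS response in percentage points.

    Positive when the stimulated cytokine-positive percentage exceeds the
    unstimulated background by at least ``threshold`` points (0.2 by
    default).
    """
    for v in (stim_percent, unstim_percent):
        if not (0 <= v <= 100):
            raise ValidationError("percentages must lie in [0, 100]")
    delta = stim_percent - unstim_percent
    return delta, delta >= threshold
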