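"""Vaccine-clone enrichment and longitudinal clone tracking.

Two repertoire samples are compared clone by clone under a binomial
framework: conditioning on the total templates K = k1 + k2 a clone received
across the pair, its split is Binomial(K, n1/(n1+n2)) when its frequency is
the same in both samples. A two-sided exact p-value per clone is adjusted
with Benjamini–Hochberg at FDR alpha (0.01 in the trial analysis); a clone
is *enriched* when its adjusted q-value passes and its template proportion
is higher in the comparator sample.

The union of clones enriched in any antigen-sorted T-cell sample versus the
subject's baseline blood forms the vaccine-associated clone set, which is
then tracked through blood and tumor samples by summing productive
frequencies of its members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import get_logger
from .repertoire import RepertoireSample

__all__ = [
    "bh_adjust",
    "build_clone_pair_table",
    "differential_abundance",
    "expanded_clones",
    "VaccineCloneSet",
    "vaccine_associated_set",
    "cumulative_vaccine_frequency",
    "expanded_clone_overlap",
]

_log = get_logger(__name__)

RESULT_COLUMNS = ["clone", "k1", "n1", "k2", "n2", "p_value", "q_value", "enriched", "direction"]


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values: q_(i) = min_{j>=i} m*p_(j)/j.

    Stable sort, monotone by construction, order-preserving with p.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def build_clone_pair_table(
    sample1: RepertoireSample, sample2: RepertoireSample
) -> pd.DataFrame:
    """Union of clones over two samples with per-sample template counts.

    Returns columns clone, k1, k2 plus attrs n1/n2 (total templates per
    sample); only clones with k1 + k2 >= 1 appear.
    """
    c1 = sample1.clonotypes.groupby("rearrangement")["templates"].sum()
    c2 = sample2.clonotypes.groupby("rearrangement")["templates"].sum()
    table = pd.concat([c1.rename("k1"), c2.rename("k2")], axis=1).fillna(0).astype(np.int64)
    table = table[table.sum(axis=1) >= 1]
    table = table.rename_axis("clone").reset_index()
    table.attrs["n1"] = sample1.total_templates
    table.attrs["n2"] = sample2.total_templates
    return table


def _two_sided_doubled_tail(k: np.ndarray, K: np.ndarray, p0: float) -> np.ndarray:
    lower = stats.binom.cdf(k, K, p0)
    upper = stats.binom.sf(k - 1, K, p0)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def _two_sided_minlike(k: np.ndarray, K: np.ndarray, p0: float) -> np.ndarray:
    # sum of outcome probabilities no larger than the observed one
    out = np.empty(k.size)
    for i, (ki, Ki) in enumerate(zip(k, K)):
        out[i] = stats.binomtest(int(ki), int(Ki), p0, alternative="two-sided").pvalue
    return out


def differential_abundance(
    baseline: RepertoireSample,
    comparator: RepertoireSample,
    alpha: float = 0.01,
    min_total: int = 2,
    method: str = "doubled_tail",
) -> pd.DataFrame:
    """Per-clone two-sided conditional binomial test with BH FDR control.

    For each clone with k1 + k2 >= ``min_total``, tests k1 successes in
    K = k1 + k2 trials against null proportion n1/(n1 + n2). ``method``
    selects the two-sided convention: ``doubled_tail`` (double the smaller
    exact tail, capped at 1; the default, recorded in result attrs) or
    ``minlike`` (minimum-likelihood outcome sum). ``enriched`` marks clones
    with q <= alpha whose proportion is higher in the comparator.
    """
    if not (0 < alpha <= 1):
        raise ValidationError("alpha must be in (0, 1]")
    if min_total < 1:
        raise ValidationError("min_total must be >= 1")
    if baseline.total_templates == 0 or comparator.total_templates == 0:
        raise ValidationError("both samples must contain templates")
    table = build_clone_pair_table(baseline, comparator)
    n1, n2 = table.attrs["n1"], table.attrs["n2"]
    table = table[(table["k1"] + table["k2"]) >= min_total].reset_index(drop=True)
    if table.empty:
        _log.warning(
            "no clones pass min_total=%d for %s vs %s",
            min_total, baseline.sample_id, comparator.sample_id,
        )
        result = pd.DataFrame(columns=RESULT_COLUMNS)
    else:
        k1 = table["k1"].to_numpy()
        K = (table["k1"] + table["k2"]).to_numpy()
        p0 = n1 / (n1 + n2)
        if method == "doubled_tail":
            p = _two_sided_doubled_tail(k1, K, p0)
        elif method == "minlike":
            p = _two_sided_minlike(k1, K, p0)
        else:
            raise ValidationError(f"unknown method {method!r}")
        q = bh_adjust(p)
        prop1 = k1 / n1
        prop2 = table["k2"].to_numpy() / n2
        direction = np.where(prop2 > prop1, "up", np.where(prop2 < prop1, "down", "none"))
        result = pd.DataFrame(
            {
                "clone": table["clone"],
                "k1": k1,
                "n1": n1,
                "k2": table["k2"],
                "n2": n2,
                "p_value": p,
                "q_value": q,
                "enriched": (q <= alpha) & (direction == "up"),
                "direction": direction,
            }
        )
    result.attrs.update(
        {"alpha": alpha, "min_total": min_total, "method": method,
         "baseline": baseline.sample_id, "comparator": comparator.sample_id}
    )
    return result


def expanded_clones(
    baseline: RepertoireSample,
    post: RepertoireSample,
    alpha: float = 0.01,
    min_total: int = 2,
    method: str = "doubled_tail",
) -> pd.DataFrame:
    """Treatment-expanded clones: the same framework with a post-treatment
    sample (blood series or on-treatment biopsy) as the comparator."""
    return differential_abundance(baseline, post, alpha=alpha, min_total=min_total, method=method)


@dataclass
class VaccineCloneSet:
    """Union of clones enriched in a subject's antigen-sorted samples.

    ``provenance`` maps each clone to the sorted samples (IDO / PD-L1) in
    which it was called enriched.
    """

    subject_id: str
    clones: set = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clones)


def vaccine_associated_set(
    subject_id: str,
    sorted_results: list[pd.DataFrame],
    labels: list[str] | None = None,
) -> VaccineCloneSet:
    """Union the enriched clones from one subject's sorted-sample tests."""
    if not sorted_results:
        raise ValidationError("at least one enrichment result is required")
    labels = labels or [
        r.attrs.get("comparator", f"sorted_{i}") for i, r in enumerate(sorted_results)
    ]
    out = VaccineCloneSet(subject_id=subject_id)
    for res, label in zip(sorted_results, labels):
        if res.empty:
            continue
        for clone in res.loc[res["enriched"], "clone"]:
            out.clones.add(clone)
            out.provenance.setdefault(clone, []).append(label)
    return out


def cumulative_vaccine_frequency(
    clone_set: VaccineCloneSet | set, sample: RepertoireSample
) -> float:
    """Summed productive frequency of set members present in ``sample``."""
    members = clone_set.clones if isinstance(clone_set, VaccineCloneSet) else set(clone_set)
    freqs = sample.productive_frequencies()
    present = freqs.index.intersection(members)
    return float(freqs.loc[present].sum())


def expanded_clone_overlap(
    expanded: pd.DataFrame | set, other: RepertoireSample
) -> tuple[int, float]:
    """Count and cumulative frequency, in ``other``, of expanded clones.

    ``expanded`` may be an enrichment result (its enriched clones are used)
    or an explicit clone-key set. Tracks e.g. biopsy-expanded clones in the
    blood across timepoints.
    """
    if isinstance(expanded, pd.DataFrame):
        clones = set(expanded.loc[expanded["enriched"], "clone"])
    else:
        clones = set(expanded)
    freqs = other.productive_frequencies()
    present = freqs.index.intersection(clones)
    return len(present), float(freqs.loc[present].sum())
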