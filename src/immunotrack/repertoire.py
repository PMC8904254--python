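"""Per-sample TCRβ repertoire summary statistics.

A sequenced repertoire is a table of clonotypes (unique CDR3 nucleotide
rearrangements) with template counts — one template approximates one input
T-cell genome. The metrics here summarise how large and how skewed the
repertoire is:

* **T-cell fraction** — total templates divided by total nucleated cells in
  the specimen; how much of the tissue is T cells.
* **Simpson clonality** — ``sqrt(sum_i p_i**2)`` over productive-clone
  frequencies ``p_i``; 1/sqrt(R) for a perfectly even repertoire of R clones,
  1 for a monoclonal one.
* **Rarefied richness** — mean number of unique productive rearrangements
  after repeatedly downsampling (without replacement) to a common template
  depth, so samples of different depth are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UnavailableMetricError, ValidationError

__all__ = [
    "ClonotypeRecord",
    "RepertoireSample",
    "t_cell_fraction",
    "simpson_clonality",
    "rarefied_richness",
    "rarefied_richness_expectation",
]

CLONOTYPE_COLUMNS = [
    "rearrangement",
    "amino_acid",
    "templates",
    "productive",
    "productive_frequency",
]


@dataclass(frozen=True)
class ClonotypeRecord:
    """One unique TCRβ rearrangement in one sample.

    The nucleotide ``rearrangement`` string is the clone identity key;
    ``productive_frequency`` is the template count divided by the sum of
    productive templates (0 for non-productive clones).
    """

    rearrangement: str
    amino_acid: str
    templates: int
    productive: bool
    productive_frequency: float = 0.0


@dataclass
class RepertoireSample:
    """A sequenced TCRβ sample: clonotype table plus cell-count metadata.

    ``clonotypes`` has columns rearrangement, amino_acid, templates,
    productive, productive_frequency. Frequencies are renormalized over
    productive templates at construction when absent or inconsistent.
    """

    sample_id: str
    clonotypes: pd.DataFrame
    total_nucleated_cells: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.clonotypes
        missing = [c for c in ("rearrangement", "templates", "productive") if c not in df.columns]
        if missing:
            raise ValidationError(f"clonotype table missing columns: {missing}")
        df = df.copy()
        if "amino_acid" not in df.columns:
            df["amino_acid"] = ""
        df["templates"] = df["templates"].astype(np.int64)
        if (df["templates"] < 0).any():
            raise ValidationError("negative template count")
        df["productive"] = df["productive"].astype(bool)
        prod_total = int(df.loc[df["productive"], "templates"].sum())
        freq = np.zeros(len(df))
        if prod_total > 0:
            mask = df["productive"].to_numpy()
            freq[mask] = df.loc[df["productive"], "templates"].to_numpy() / prod_total
        df["productive_frequency"] = freq
        self.clonotypes = df[CLONOTYPE_COLUMNS].reset_index(drop=True)
        if self.total_nucleated_cells is not None:
            if self.total_nucleated_cells <= 0:
                raise ValidationError("total_nucleated_cells must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def total_templates(self) -> int:
        """Sum of templates over all clonotypes (productive or not)."""
        return int(self.clonotypes["templates"].sum())

    @property
    def productive_templates(self) -> int:
        return int(self.clonotypes.loc[self.clonotypes["productive"], "templates"].sum())

    @property
    def n_productive_rearrangements(self) -> int:
        """R: unique productive rearrangements with at least one template."""
        df = self.clonotypes
        return int(((df["productive"]) & (df["templates"] > 0)).sum())

    def productive_frequencies(self) -> pd.Series:
        """Productive-clone frequencies indexed by rearrangement."""
        df = self.clonotypes
        prod = df[df["productive"] & (df["templates"] > 0)]
        return prod.set_index("rearrangement")["productive_frequency"]


def t_cell_fraction(sample: RepertoireSample, productive_only: bool = False) -> float:
    """Total T-cell templates over total nucleated cells.

    ``productive_only`` restricts the numerator to productive templates
    (sensitivity analysis); the default counts every template.
    """
    if sample.total_nucleated_cells is None:
        raise UnavailableMetricError(
            f"sample {sample.sample_id}: nucleated-cell count unknown"
        )
    numer = sample.productive_templates if productive_only else sample.total_templates
    if numer > sample.total_nucleated_cells:
        raise ValidationError(
            f"sample {sample.sample_id}: templates ({numer}) exceed "
            f"nucleated cells ({sample.total_nucleated_cells})"
        )
    return numer / sample.total_nucleated_cells


def simpson_clonality(sample: RepertoireSample) -> float:
    """sqrt(sum of squared productive frequencies); in [1/sqrt(R), 1]."""
    p = sample.productive_frequencies().to_numpy()
    if p.size == 0:
        raise UnavailableMetricError(
            f"sample {sample.sample_id}: no productive clones"
        )
    return float(np.sqrt(np.sum(p**2)))


def rarefied_richness(
    sample: RepertoireSample,
    depth: int,
    n_draws: int = 5,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Mean unique productive rearrangements across ``n_draws`` subsamples.

    Each draw takes ``depth`` templates without replacement from the
    productive template pool (a multivariate hypergeometric draw on the
    count vector, which is distributionally identical to enumerating
    templates) and counts the clones that received at least one template.
    """
    df = sample.clonotypes
    counts = df.loc[df["productive"] & (df["templates"] > 0), "templates"].to_numpy()
    total = int(counts.sum())
    if depth > total:
        raise ValidationError(
            f"rarefaction depth {depth} exceeds productive templates {total}"
        )
    if depth < 0:
        raise ValidationError("depth must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    richness = np.empty(n_draws)
    for i in range(n_draws):
        draw = rng.multivariate_hypergeometric(counts, depth)
        richness[i] = np.count_nonzero(draw)
    return float(richness.mean())


def rarefied_richness_expectation(counts: np.ndarray, depth: int) -> float:
    """Closed-form expected richness: sum_i 1 - C(N-n_i, d)/C(N, d).

    The inclusion probability of clone i under sampling without replacement
    is hypergeometric; this is the analytic mean the Monte-Carlo estimator
    targets, used as an independent oracle.
    """
    from scipy.special import gammaln

    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    n_total = int(counts.sum())
    if depth > n_total:
        raise ValidationError("depth exceeds total counts")

    def log_comb(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = n_total - counts
    p_excl = np.where(
        rest >= depth,
        np.exp(log_comb(rest, depth) - log_comb(np.array(n_total), depth)),
        0.0,
    )
    return float(np.sum(1.0 - p_excl))
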