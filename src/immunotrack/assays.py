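"""Auxiliary assay computations: expression-panel QC and normalization,
RT-qPCR relative expression, the immunohistochemistry H-score, and the
CD8-centered PD-L1 proximity index on 2-D cell maps.

The expression-panel rules mirror the standard nCounter-style workflow:
per-sample QC on binding density and positive-control linearity, background
thresholding at mean + 2 SD of negative probes, scaling by a
positive-control normalization factor, then by a housekeeping factor built
from the most stable housekeeping genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .errors import UnavailableMetricError, ValidationError

__all__ = [
    "CountPanel",
    "panel_qc_normalize",
    "select_stable_housekeeping",
    "delta_ct_expression",
    "h_score",
    "CellMap",
    "proximity_index",
]

PROBE_CLASSES = ("endogenous", "positive", "negative", "housekeeping")
CELL_PHENOTYPES = ("CD8", "PDL1", "other")


@dataclass
class CountPanel:
    """Raw counts for a probe panel across samples.

    ``counts``: probes x samples DataFrame; ``probe_class``: Series mapping
    probe -> class; ``positive_concentration``: known input concentrations
    of the positive probes; ``binding_density``: per-sample imaging QC
    metric.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    positive_concentration: pd.Series
    binding_density: pd.Series

    def __post_init__(self) -> None:
        bad = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise ValidationError(f"unknown probe class(es): {sorted(bad)}")
        if (self.counts < 0).any().any():
            raise ValidationError("counts must be nonnegative")
        if (self.probe_class == "negative").sum() < 3:
            raise ValidationError("QC requires >=3 negative probes")
        if (self.probe_class == "positive").sum() < 3:
            raise ValidationError("QC requires >=3 positive probes")

    def probes_of(self, cls: str) -> pd.Index:
        return self.probe_class.index[self.probe_class == cls]


def _geomean(frame: pd.DataFrame) -> pd.Series:
    return np.exp(np.log(frame.clip(lower=1)).mean(axis=0))


def select_stable_housekeeping(
    normalized: pd.DataFrame, hk_probes: pd.Index, min_genes: int = 3
) -> pd.Index:
    """Housekeeping genes below the mean-variance trend of log counts.

    Fits a linear variance-versus-mean trend across the housekeeping genes
    on log2 counts and keeps genes with negative residual variance (more
    stable than the trend predicts), topping up to ``min_genes`` by smallest
    residual.
    """
    hk = np.log2(normalized.loc[hk_probes] + 1)
    mean, var = hk.mean(axis=1), hk.var(axis=1, ddof=1)
    if len(hk_probes) <= min_genes:
        return hk_probes
    slope, intercept = np.polyfit(mean, var, 1)
    resid = var - (slope * mean + intercept)
    stable = resid.index[resid < 0]
    if len(stable) < min_genes:
        stable = resid.nsmallest(min_genes).index
    return pd.Index(stable)


def panel_qc_normalize(
    panel: CountPanel,
    background: str = "floor",
    binding_density_range: tuple[float, float] = (0.05, 2.25),
    r2_min: float = 0.75,
    positive_factor_range: tuple[float, float] = (0.3, 3.0),
    housekeeping_factor_range: tuple[float, float] = (0.1, 10.0),
    positive_reference: float | None = None,
    housekeeping_reference: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """QC and normalize a count panel; returns (normalized counts, QC table).

    Per sample: (1) fail on binding density outside the accepted range;
    (2) fail when the positive-control counts-vs-concentration regression
    has R^2 below ``r2_min``; (3) remove background at mean + 2 SD of the
    negative probes (``background='floor'`` zeroes counts below threshold,
    ``'subtract'`` subtracts it and clips at zero); (4) scale by the
    positive factor (mean of per-sample positive-control geometric means
    over this sample's), failing outside its range; (5) scale by the
    housekeeping factor from stable housekeeping genes, failing outside its
    range. The normalized matrix contains passing samples only.

    Factor numerators default to the across-sample mean of per-sample
    geometric means (the usual panel convention). Because that reference
    moves with the data, a single sample's normalized counts are then
    invariant to rescaling that sample only up to a panel-wide factor;
    passing fixed ``positive_reference`` / ``housekeeping_reference``
    values (e.g. from a reference run) makes per-sample normalization
    exactly scale-free.
    """
    if background not in ("floor", "subtract"):
        raise ValidationError(f"unknown background mode {background!r}")
    counts = panel.counts.astype(float)
    samples = counts.columns
    neg, pos = panel.probes_of("negative"), panel.probes_of("positive")
    hk, endo = panel.probes_of("housekeeping"), panel.probes_of("endogenous")

    qc = pd.DataFrame(index=samples)
    qc["binding_density"] = panel.binding_density.reindex(samples)
    qc["binding_density_pass"] = qc["binding_density"].between(*binding_density_range)

    conc = panel.positive_concentration.reindex(pos)
    r2 = {}
    for s in samples:
        lr = stats.linregress(conc.to_numpy(), counts.loc[pos, s].to_numpy())
        r2[s] = lr.rvalue**2
    qc["positive_r2"] = pd.Series(r2)
    qc["linearity_pass"] = qc["positive_r2"] >= r2_min

    # background removal (per-sample threshold from that sample's negatives)
    thresh = counts.loc[neg].mean(axis=0) + 2 * counts.loc[neg].std(axis=0, ddof=1)
    if background == "floor":
        bg_removed = counts.where(counts.ge(thresh, axis=1), 0.0)
    else:
        bg_removed = (counts.sub(thresh, axis=1)).clip(lower=0.0)

    pos_geo = _geomean(bg_removed.loc[pos])
    pos_factor = (positive_reference or pos_geo.mean()) / pos_geo
    qc["positive_factor"] = pos_factor
    qc["positive_factor_pass"] = pos_factor.between(*positive_factor_range)
    pos_normed = bg_removed.mul(pos_factor, axis=1)

    if len(hk) == 0:
        raise ValidationError("no housekeeping probes for second normalization")
    stable = select_stable_housekeeping(pos_normed, hk)
    hk_geo = _geomean(pos_normed.loc[stable])
    hk_factor = (housekeeping_reference or hk_geo.mean()) / hk_geo
    qc["housekeeping_factor"] = hk_factor
    qc["housekeeping_factor_pass"] = hk_factor.between(*housekeeping_factor_range)
    qc["stable_housekeeping"] = ",".join(stable)

    qc["pass"] = (
        qc["binding_density_pass"] & qc["linearity_pass"]
        & qc["positive_factor_pass"] & qc["housekeeping_factor_pass"]
    )
    normalized = pos_normed.mul(hk_factor, axis=1).loc[
        endo.union(hk, sort=False), qc.index[qc["pass"]]
    ]
    return normalized, qc


def delta_ct_expression(
    target_ct: float,
    housekeeping_ct: float,
    control_target_ct: float,
    control_housekeeping_ct: float,
    ct_ceiling: float = 40.0,
) -> float:
    """Relative expression by the ddCt method: 2**-ddCt.

    dCt = target - housekeeping in each sample; ddCt = dCt(sample) -
    dCt(control). Missing amplification (NaN) is mapped to the Ct ceiling
    (40 cycles by default).
    """
    cts = []
    for ct in (target_ct, housekeeping_ct, control_target_ct, control_housekeeping_ct):
        ct = ct_ceiling if ct is None or np.isnan(ct) else float(ct)
        if not (0 < ct <= ct_ceiling):
            raise ValidationError(f"Ct {ct} outside (0, {ct_ceiling}]")
        cts.append(ct)
    ddct = (cts[0] - cts[1]) - (cts[2] - cts[3])
    return float(2.0 ** (-ddct))


def h_score(percent_strong: float, percent_moderate: float, percent_weak: float) -> float:
    """Immunohistochemistry H-score: 3*strong% + 2*moderate% + weak%, 0-300."""
    s, m, w = percent_strong, percent_moderate, percent_weak
    if min(s, m, w) < 0:
        raise ValidationError("percentages must be nonnegative")
    if s + m + w > 100 + 1e-9:
        raise ValidationError("staining percentages exceed 100")
    return 3.0 * s + 2.0 * m + w


@dataclass
class CellMap:
    """2-D cell coordinates (micrometres) with phenotype labels."""

    x_um: np.ndarray
    y_um: np.ndarray
    phenotype: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=object)
        if not (len(self.x_um) == len(self.y_um) == len(self.phenotype)):
            raise ValidationError("coordinate and phenotype arrays differ in length")
        if not (np.isfinite(self.x_um).all() and np.isfinite(self.y_um).all()):
            raise ValidationError("coordinates must be finite")
        bad = set(self.phenotype) - set(CELL_PHENOTYPES)
        if bad:
            raise ValidationError(f"unknown phenotype label(s): {sorted(bad)}")

    def coords_of(self, label: str) -> np.ndarray:
        mask = self.phenotype == label
        return np.column_stack([self.x_um[mask], self.y_um[mask]])


def proximity_index(cell_map: CellMap, cutoff_um: float) -> float:
    """Percentage of CD8+ cells with >=1 PD-L1+ cell within ``cutoff_um``.

    Conventional cutoffs are 20, 40, 60 and 80 micrometres; any positive
    distance is accepted. Neighbor lookup uses a spatial tree; results are
    identical to the brute-force all-pairs distance computation.
    """
    if cutoff_um <= 0:
        raise ValidationError("cutoff must be positive")
    cd8 = cell_map.coords_of("CD8")
    if len(cd8) == 0:
        raise UnavailableMetricError("no CD8 cells in map")
    pdl1 = cell_map.coords_of("PDL1")
    if len(pdl1) == 0:
        return 0.0
    tree = cKDTree(pdl1)
    dist, _ = tree.query(cd8, k=1)
    return 100.0 * float(np.mean(dist <= cutoff_um))
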