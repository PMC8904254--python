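"""Synthetic data with the statistical structure the analyses assume.

Every generator is deterministic given a seed and produces objects that
satisfy the consuming module's type invariants, with known ground truth for
recovery tests:

* repertoires — power-law (Zipf) or log-normal clone-abundance laws with
  designated vaccine-reactive clones that expand by a per-timepoint fold and
  are partially shared between blood and tumor; template counts are a
  multinomial draw at the sequencing depth;
* antigen-sorted samples — vaccine clones of one antigen occupy a given
  purity of the template mass over the background repertoire;
* ELISPOT plates — overdispersed (negative-binomial) replicate spot counts;
* cohorts — trial/control patients with discrete covariates drawn from
  stated marginals, logistic response, Weibull progression-free and overall
  survival by response stratum, and independent censoring;
* cell maps — homogeneous Poisson phenotype point patterns, optionally with
  PD-L1 cells attracted to within a radius of CD8 cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elispot import ElispotAssay
from .errors import ValidationError
from .io import stream_rng
from .repertoire import RepertoireSample
from .assays import CellMap

__all__ = [
    "RepertoireModel",
    "CohortModel",
    "gen_repertoire",
    "gen_sorted_sample",
    "gen_elispot",
    "gen_cohort",
    "gen_cell_map",
]


@dataclass
class RepertoireModel:
    """Ground-truth clone-abundance model for one subject.

    Baseline frequencies follow rank**(-zipf_exponent) (or a log-normal law
    when ``abundance='lognormal'``). ``vaccine_clones`` maps clone index ->
    antigen; ``expansion_fold`` maps timepoint -> multiplicative fold applied
    to vaccine-clone frequencies before renormalization. A fraction of
    clones is non-productive (out-of-frame), and ``sharing_fraction`` of
    clones is present in both blood and tumor.
    """

    # exponent 1.0 puts baseline Simpson clonality near 0.14 at these
    # defaults, inside the 0.05-0.2 band typical of blood repertoires
    n_clones: int = 5_000
    abundance: str = "zipf"
    zipf_exponent: float = 1.0
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    depth: int = 20_000
    non_productive_fraction: float = 0.15
    vaccine_clones: dict = field(default_factory=dict)   # clone idx -> 'IDO'|'PDL1'
    expansion_fold: dict = field(default_factory=dict)   # timepoint -> fold
    sharing_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.sharing_fraction <= 1):
            raise ValidationError("sharing_fraction must lie in [0, 1]")
        if any(f < 0 for f in self.expansion_fold.values()):
            raise ValidationError("expansion folds must be nonnegative")

    def base_frequencies(self) -> np.ndarray:
        ranks = np.arange(1, self.n_clones + 1, dtype=float)
        if self.abundance == "zipf":
            w = ranks ** (-self.zipf_exponent)
        elif self.abundance == "lognormal":
            rng = stream_rng(self.seed, "abundance-law")
            w = rng.lognormal(self.lognormal_mu, self.lognormal_sigma, self.n_clones)
        else:
            raise ValidationError(f"unknown abundance law {self.abundance!r}")
        return w / w.sum()


def _clone_table(
    model: RepertoireModel, freqs: np.ndarray, depth: int, rng: np.random.Generator
) -> pd.DataFrame:
    counts = rng.multinomial(depth, freqs)
    nonprod_rng = stream_rng(model.seed, "frame-status")
    productive = nonprod_rng.random(model.n_clones) >= model.non_productive_fraction
    if model.vaccine_clones:
        # vaccine-reactive clones encode functional receptors by construction
        productive[np.fromiter(model.vaccine_clones.keys(), dtype=int)] = True
    keep = counts > 0
    return pd.DataFrame(
        {
            "rearrangement": [f"clone{int(i):05d}" for i in np.flatnonzero(keep)],
            "amino_acid": "",
            "templates": counts[keep],
            "productive": productive[keep],
        }
    )


def gen_repertoire(
    model: RepertoireModel,
    timepoint: str = "baseline",
    sample_id: str | None = None,
    total_nucleated_cells: int | None = None,
) -> RepertoireSample:
    """Sample a repertoire at a timepoint, expanding vaccine clones.

    Vaccine-clone frequencies are multiplied by the timepoint's fold and the
    vector renormalized, then templates are a multinomial draw at the
    model's depth. Deterministic per (model.seed, timepoint).
    """
    if model.depth < 1:
        raise ValidationError("sequencing depth must be >= 1")
    freqs = model.base_frequencies().copy()
    fold = model.expansion_fold.get(timepoint, 1.0)
    if model.vaccine_clones and fold != 1.0:
        idx = np.fromiter(model.vaccine_clones.keys(), dtype=int)
        freqs[idx] *= fold
        freqs /= freqs.sum()
    rng = stream_rng(model.seed, f"repertoire-{timepoint}")
    table = _clone_table(model, freqs, model.depth, rng)
    return RepertoireSample(
        sample_id=sample_id or f"sim_{timepoint}",
        clonotypes=table,
        total_nucleated_cells=total_nucleated_cells,
    )


def gen_sorted_sample(
    model: RepertoireModel,
    antigen: str,
    purity: float = 0.9,
    depth: int | None = None,
    sample_id: str | None = None,
) -> RepertoireSample:
    """An antigen-sorted T-cell culture: vaccine clones at ``purity`` mass.

    Vaccine clones of the requested antigen share ``purity`` of the template
    mass in proportion to their baseline frequencies; the background
    repertoire fills the remainder.
    """
    if not (0 < purity <= 1):
        raise ValidationError("purity must lie in (0, 1]")
    idx = np.fromiter(
        (i for i, a in model.vaccine_clones.items() if a == antigen), dtype=int
    )
    if idx.size == 0:
        raise ValidationError(f"model has no vaccine clones for antigen {antigen!r}")
    base = model.base_frequencies()
    freqs = np.zeros_like(base)
    vac = base[idx] / base[idx].sum()
    freqs[idx] = purity * vac
    if purity < 1:
        bg = base.copy()
        bg[idx] = 0.0
        freqs += (1 - purity) * bg / bg.sum()
    rng = stream_rng(model.seed, f"sorted-{antigen}")
    table = _clone_table(model, freqs, depth or model.depth, rng)
    return RepertoireSample(sample_id=sample_id or f"sim_sorted_{antigen}", clonotypes=table)


def gen_elispot(
    mu_control: float,
    effect: float,
    dispersion: float = 5.0,
    replicates: int = 3,
    seed: int = 0,
    subject_id: str = "sim",
    timepoint: str = "C3",
    antigen: str = "IDO",
) -> ElispotAssay:
    """Negative-binomial replicate spot counts.

    Control wells have mean ``mu_control``; antigen wells ``mu_control +
    effect``. ``dispersion`` is the NB size parameter r (variance =
    mu + mu^2/r); smaller r means more overdispersion.
    """
    rng = stream_rng(seed, f"elispot-{subject_id}-{timepoint}-{antigen}")

    def draw(mu: float) -> list[int]:
        p = dispersion / (dispersion + mu)
        return [int(v) for v in rng.negative_binomial(dispersion, p, replicates)]

    return ElispotAssay(
        subject_id=subject_id,
        timepoint=timepoint,
        antigen=antigen,
        antigen_wells=draw(mu_control + effect),
        control_wells=draw(mu_control),
        cells_per_well=300_000,
    )


@dataclass
class CohortModel:
    """Generative model for patient-level trial/control cohorts.

    Default covariate marginals follow a metastatic-melanoma population:
    elevated LDH 37%, M1c 60%, BRAF mutated 37%, PD-L1 <1% 43%, male 60%,
    age >70 30%. Response is Bernoulli on a logistic scale with an arm
    effect and optional covariate effects; PFS and OS are Weibull draws by
    response stratum with independent uniform censoring.
    """

    p_elevated_ldh: float = 0.37
    p_m1c: float = 0.60
    p_braf_mutated: float = 0.37
    p_pdl1_low: float = 0.43
    p_male: float = 0.60
    p_over70: float = 0.30
    control_logit: float = -0.3          # control-arm response log-odds
    arm_log_or: float = 1.5              # trial-vs-control log odds ratio
    covariate_logit: dict = field(default_factory=dict)  # covariate -> coefficient
    #: Weibull (shape, scale months) per (endpoint, responder?) stratum
    pfs_weibull: dict = field(
        default_factory=lambda: {True: (1.3, 30.0), False: (1.1, 6.0)}
    )
    os_weibull: dict = field(
        default_factory=lambda: {True: (1.3, 60.0), False: (1.1, 18.0)}
    )
    censor_max_months: float = 48.0
    seed: int = 0


_COVARIATE_LEVELS = {
    "age_group": ("<=70", ">70"),
    "sex": ("female", "male"),
    "ldh": ("normal", "elevated"),
    "m_stage": ("M1a", "M1b", "M1c"),
    "braf": ("wild type", "mutated"),
    "pdl1": ("<1%", ">=1%"),
}


def gen_cohort(model: CohortModel, n_trial: int, n_control: int) -> pd.DataFrame:
    """Patient-level table for both arms with response and survival.

    Columns match the matching/regression machinery: arm, the six matching
    covariates, response (CR/PR/SD/PD), pfs/os months and event flags.
    """
    rng = stream_rng(model.seed, "cohort")
    n = n_trial + n_control
    arm = np.array(["trial"] * n_trial + ["control"] * n_control)

    over70 = rng.random(n) < model.p_over70
    male = rng.random(n) < model.p_male
    ldh = rng.random(n) < model.p_elevated_ldh
    braf = rng.random(n) < model.p_braf_mutated
    pdl1_low = rng.random(n) < model.p_pdl1_low
    m1c = rng.random(n) < model.p_m1c
    m_stage = np.where(m1c, "M1c", np.where(rng.random(n) < 0.5, "M1a", "M1b"))

    logit = model.control_logit + model.arm_log_or * (arm == "trial")
    cov_values = {
        "age_group": over70, "sex": male, "ldh": ldh,
        "braf": braf, "pdl1": pdl1_low, "m_stage": m1c,
    }
    for name, coef in model.covariate_logit.items():
        logit = logit + coef * cov_values[name].astype(float)
    responder = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    # split responders into CR/PR and non-responders into SD/PD
    cr = responder & (rng.random(n) < 0.5)
    sd = ~responder & (rng.random(n) < 0.5)
    response = np.where(cr, "CR", np.where(responder, "PR", np.where(sd, "SD", "PD")))

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "arm": arm,
            "age_group": np.where(over70, ">70", "<=70"),
            "sex": np.where(male, "male", "female"),
            "ldh": np.where(ldh, "elevated", "normal"),
            "m_stage": m_stage,
            "braf": np.where(braf, "mutated", "wild type"),
            "pdl1": np.where(pdl1_low, "<1%", ">=1%"),
            "response": response,
        }
    )
    for endpoint, params in (("pfs", model.pfs_weibull), ("os", model.os_weibull)):
        t = np.empty(n)
        for resp_stratum, (shape, scale) in params.items():
            mask = responder == resp_stratum
            t[mask] = scale * rng.weibull(shape, int(mask.sum()))
        censor = rng.uniform(0, model.censor_max_months, n)
        df[f"{endpoint}_months"] = np.minimum(t, censor)
        df[f"{endpoint}_event"] = (t <= censor).astype(int)
    return df


def gen_cell_map(
    n_cd8: int,
    n_pdl1: int,
    field_um: float = 1000.0,
    clustering: str = "none",
    attract_radius_um: float = 5.0,
    n_other: int = 0,
    seed: int = 0,
) -> CellMap:
    """Point pattern of CD8/PD-L1/other cells on a square field.

    ``clustering='none'`` places every phenotype uniformly (homogeneous
    Poisson given counts); ``'attract'`` places each PD-L1 cell uniformly in
    a disk of ``attract_radius_um`` around a CD8 cell, cycling through the
    CD8 cells in shuffled order so that with ``n_pdl1 >= n_cd8`` every CD8
    cell gets a nearby PD-L1 neighbor.
    """
    if clustering not in ("none", "attract"):
        raise ValidationError(f"unknown clustering mode {clustering!r}")
    if clustering == "attract" and n_cd8 == 0 and n_pdl1 > 0:
        raise ValidationError("attract mode requires at least one CD8 cell")
    rng = stream_rng(seed, "cellmap")
    cd8 = rng.uniform(0, field_um, (n_cd8, 2))
    other = rng.uniform(0, field_um, (n_other, 2))
    if clustering == "none" or n_pdl1 == 0:
        pdl1 = rng.uniform(0, field_um, (n_pdl1, 2))
    else:
        centers = cd8[np.resize(rng.permutation(n_cd8), n_pdl1)]
        r = attract_radius_um * np.sqrt(rng.random(n_pdl1))
        theta = rng.uniform(0, 2 * np.pi, n_pdl1)
        pdl1 = centers + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    xy = np.vstack([cd8, pdl1, other])
    labels = np.array(["CD8"] * n_cd8 + ["PDL1"] * n_pdl1 + ["other"] * n_other, dtype=object)
    return CellMap(x_um=xy[:, 0], y_um=xy[:, 1], phenotype=labels)
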