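"""End-to-end orchestration: subject-level repertoire/ELISPOT analysis and
cohort-level clinical comparison, from a single validated configuration.

Outputs are plain CSV/JSON plus a machine-readable run manifest recording
parameters, seeds and the package version, so a run can be reproduced
bit-for-bit from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import (
    exact_match,
    km_estimate,
    response_tally,
    reverse_km_followup,
    weighted_cox,
    weighted_logistic,
)
from .dynamics import (
    cumulative_vaccine_frequency,
    differential_abundance,
    vaccine_associated_set,
)
from .elispot import ElispotAssay, classify_response
from .errors import ImmunotrackError, ValidationError
from .io import get_logger, read_manifest, read_repertoire_tsv
from .repertoire import rarefied_richness, simpson_clonality, t_cell_fraction

__all__ = ["RunConfig", "run_subject_pipeline", "run_cohort_pipeline", "PipelineError"]

_log = get_logger(__name__)


class PipelineError(ImmunotrackError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated parameters for a pipeline run."""

    out_dir: str
    manifest: str | None = None
    elispot_plates: str | None = None
    cohort: str | None = None
    alpha: float = 0.01
    min_total: int = 2
    rarefaction_depth: str | int = "auto"
    rarefaction_draws: int = 5
    dfr_variant: str = "eq"
    ci_method: str = "wilson"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValidationError(f"alpha {self.alpha} outside (0, 1]")
        if self.min_total < 1:
            raise ValidationError("min_total must be >= 1")
        if self.dfr_variant not in ("eq", "2x"):
            raise ValidationError(f"unknown DFR variant {self.dfr_variant!r}")
        if self.ci_method not in ("wilson", "clopper_pearson", "logit_wald"):
            raise ValidationError(f"unknown CI method {self.ci_method!r}")
        if self.rarefaction_depth != "auto" and int(self.rarefaction_depth) < 1:
            raise ValidationError("rarefaction depth must be 'auto' or a positive integer")
        for attr in ("manifest", "elispot_plates", "cohort"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise ValidationError(f"{attr} path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def _run_manifest(config: RunConfig, outputs: list[str], out_dir: Path) -> None:
    _write_json(
        {"version": __version__, "parameters": asdict(config), "outputs": sorted(outputs)},
        out_dir / "run_manifest.json",
    )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ImmunotrackError as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapper
    return deco


@_stage("load-samples")
def _load_samples(config: RunConfig):
    entries = read_manifest(config.manifest)
    base = Path(config.manifest).parent
    samples = {}
    for entry in entries:
        path = Path(entry.file_path)
        if not path.is_absolute():
            path = base / path
        samples[entry.sample_id] = read_repertoire_tsv(
            path, sample_id=entry.sample_id,
            total_nucleated_cells=entry.total_nucleated_cells,
        )
    return entries, samples


@_stage("metrics")
def _metrics_table(config: RunConfig, entries, samples) -> pd.DataFrame:
    if config.rarefaction_depth == "auto":
        depth = min(s.productive_templates for s in samples.values())
    else:
        depth = int(config.rarefaction_depth)
    rows = []
    for entry in entries:
        s = samples[entry.sample_id]
        try:
            tcf = t_cell_fraction(s)
        except ImmunotrackError:
            tcf = np.nan
        rows.append(
            {
                "sample_id": s.sample_id,
                "subject_id": entry.subject_id,
                "compartment": entry.compartment,
                "timepoint": entry.timepoint,
                "total_templates": s.total_templates,
                "t_cell_fraction": tcf,
                "simpson_clonality": simpson_clonality(s),
                "rarefied_richness": rarefied_richness(
                    s, depth, n_draws=config.rarefaction_draws, seed=config.seed
                ),
            }
        )
    return pd.DataFrame(rows)


def run_subject_pipeline(config: RunConfig) -> dict:
    """Metrics -> sorted-sample enrichment -> vaccine set -> tracking
    (-> ELISPOT calls), written as a per-subject report bundle.

    Returns a dict of output paths. Any stage failure aborts with an error
    naming the stage.
    """
    if config.manifest is None:
        raise ValidationError("subject pipeline requires a manifest")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    entries, samples = _load_samples(config)
    metrics = _metrics_table(config, entries, samples)
    metrics.to_csv(out_dir / "metrics.csv", index=False)
    outputs["metrics"] = str(out_dir / "metrics.csv")

    by_subject: dict[str, list] = {}
    for e in entries:
        by_subject.setdefault(e.subject_id, []).append(e)

    vaccine_sets = {}
    tracking_rows = []
    for subject, subj_entries in by_subject.items():
        baseline = next(
            (e for e in subj_entries
             if e.compartment == "blood" and e.timepoint == "baseline"),
            None,
        )
        sorted_entries = [e for e in subj_entries if e.compartment == "sorted_specific"]
        if baseline is None or not sorted_entries:
            continue
        results, labels = [], []
        for e in sorted_entries:
            res = differential_abundance(
                samples[baseline.sample_id], samples[e.sample_id],
                alpha=config.alpha, min_total=config.min_total,
            )
            fname = out_dir / f"enrichment_{e.sample_id}.csv"
            res.to_csv(fname, index=False)
            outputs[f"enrichment_{e.sample_id}"] = str(fname)
            results.append(res)
            labels.append(e.sample_id)
        vset = vaccine_associated_set(subject, results, labels)
        vaccine_sets[subject] = {
            "clones": sorted(vset.clones),
            "provenance": {k: sorted(v) for k, v in vset.provenance.items()},
        }
        for e in subj_entries:
            if e.compartment == "sorted_specific":
                continue
            s = samples[e.sample_id]
            freqs = s.productive_frequencies()
            present = freqs.index.intersection(vset.clones)
            tracking_rows.append(
                {
                    "sample_id": e.sample_id,
                    "subject_id": subject,
                    "timepoint": e.timepoint,
                    "compartment": e.compartment,
                    "n_set_members_present": len(present),
                    "cumulative_frequency": cumulative_vaccine_frequency(vset, s),
                }
            )
    _write_json(vaccine_sets, out_dir / "vaccine_sets.json")
    outputs["vaccine_sets"] = str(out_dir / "vaccine_sets.json")
    pd.DataFrame(
        tracking_rows,
        columns=["sample_id", "subject_id", "timepoint", "compartment",
                 "n_set_members_present", "cumulative_frequency"],
    ).to_csv(out_dir / "tracking.csv", index=False)
    outputs["tracking"] = str(out_dir / "tracking.csv")

    if config.elispot_plates is not None:
        calls = _elispot_calls(config)
        calls.to_csv(out_dir / "elispot_calls.csv", index=False)
        outputs["elispot_calls"] = str(out_dir / "elispot_calls.csv")

    _run_manifest(config, list(outputs.values()), out_dir)
    outputs["run_manifest"] = str(out_dir / "run_manifest.json")
    return outputs


@_stage("elispot")
def _elispot_calls(config: RunConfig) -> pd.DataFrame:
    plates = pd.read_csv(config.elispot_plates)
    needed = {"subject", "timepoint", "antigen", "condition", "spots"}
    missing = needed - set(plates.columns)
    if missing:
        raise ValidationError(f"plate CSV missing column(s): {sorted(missing)}")
    rows = []
    for (subject, timepoint, antigen), grp in plates.groupby(
        ["subject", "timepoint", "antigen"], sort=True
    ):
        assay = ElispotAssay(
            subject_id=str(subject),
            timepoint=str(timepoint),
            antigen=str(antigen),
            antigen_wells=grp.loc[grp["condition"] == "antigen", "spots"].tolist(),
            control_wells=grp.loc[grp["condition"] == "control", "spots"].tolist(),
        )
        call = classify_response(assay, variant=config.dfr_variant, seed=config.seed)
        rows.append(
            {"subject": subject, "timepoint": timepoint, "antigen": antigen,
             "magnitude": call.magnitude, "p_value": call.p_value, "call": call.call}
        )
    return pd.DataFrame(rows)


def run_cohort_pipeline(config: RunConfig) -> dict:
    """Exact matching, weighted effect estimates and survival curves from a
    patient-level cohort CSV with trial and control arms."""
    if config.cohort is None:
        raise ValidationError("cohort pipeline requires a cohort table")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    df = pd.read_csv(config.cohort)
    if "arm" not in df.columns:
        raise PipelineError("stage load-cohort: cohort CSV lacks an 'arm' column")
    cases = df[df["arm"] == "trial"]
    controls = df[df["arm"] == "control"]

    try:
        cohort = exact_match(cases, controls)
    except ImmunotrackError as exc:
        raise PipelineError(f"stage matching: {exc}") from exc
    cohort.to_frame().to_csv(out_dir / "matched_cohort.csv", index=False)
    outputs["matched_cohort"] = str(out_dir / "matched_cohort.csv")

    effects: dict = {
        "n_cases": len(cohort.cases),
        "n_controls": len(cohort.controls),
        "n_unmatched_cases": len(cohort.unmatched_cases),
    }
    try:
        effects["response"] = weighted_logistic(cohort)
    except ImmunotrackError as exc:
        raise PipelineError(f"stage logistic: {exc}") from exc
    for endpoint in ("pfs", "os"):
        if f"{endpoint}_months" in df.columns:
            try:
                effects[endpoint] = weighted_cox(cohort, endpoint=endpoint)
            except ImmunotrackError as exc:
                raise PipelineError(f"stage cox-{endpoint}: {exc}") from exc
    tally = response_tally(cohort.cases["response"], method=config.ci_method)
    effects["trial_tally"] = tally.to_dict(orient="records")
    if "pfs_months" in cohort.cases.columns:
        effects["median_followup_months"] = reverse_km_followup(
            cohort.cases["pfs_months"], cohort.cases["pfs_event"]
        )
    _write_json(effects, out_dir / "effects.json")
    outputs["effects"] = str(out_dir / "effects.json")

    for arm_name, arm_df in (("trial", cohort.cases), ("control", cohort.controls)):
        if "pfs_months" not in arm_df.columns:
            continue
        curve = km_estimate(arm_df["pfs_months"], arm_df["pfs_event"])
        fname = out_dir / f"km_pfs_{arm_name}.csv"
        curve.to_frame().to_csv(fname, index=False)
        outputs[f"km_pfs_{arm_name}"] = str(fname)

    _run_manifest(config, list(outputs.values()), out_dir)
    outputs["run_manifest"] = str(out_dir / "run_manifest.json")
    return outputs
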