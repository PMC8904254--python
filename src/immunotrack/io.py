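"""Readers and writers for repertoire TSVs, sample manifests, and seeding.

Clone tables follow the immunoSEQ convention: one row per unique CDR3
nucleotide rearrangement with a template count and a productive flag.
Two dialects are accepted out of the box — a minimal four-column export
(``rearrangement``, ``amino_acid``, ``templates``, ``productive``) and a
verbose vendor-style header (``frame_type`` in {In, Out, Stop} instead of a
boolean) — and any other header can be adapted with a ``column_map``.
Frequencies are stored as fractions in [0, 1].
"""

from __future__ import annotations

import logging
import sys
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .repertoire import RepertoireSample

__all__ = [
    "TIMEPOINTS",
    "COMPARTMENTS",
    "ANTIGENS",
    "SampleManifestEntry",
    "read_repertoire_tsv",
    "write_repertoire_tsv",
    "read_manifest",
    "write_manifest",
    "stream_rng",
    "get_logger",
]

#: Ordered on-study timepoint labels (baseline, cycle 3/6/12, 3 and 6 months
#: after the last vaccine).
TIMEPOINTS = ("baseline", "C3", "C6", "C12", "post3m", "post6m")
COMPARTMENTS = ("blood", "tumor", "sorted_specific", "skil")
ANTIGENS = ("IDO", "PDL1", "mixed", "none")

#: Verbose immunoSEQ-style header mapped onto the canonical minimal columns.
IMMUNOSEQ_COLUMN_MAP = {
    "rearrangement": "rearrangement",
    "amino_acid": "amino_acid",
    "templates": "templates",
    "frame_type": "frame_type",
}


@dataclass(frozen=True)
class SampleManifestEntry:
    """One sequenced sample in a study manifest."""

    sample_id: str
    subject_id: str
    compartment: str
    antigen: str
    timepoint: str
    file_path: str
    total_nucleated_cells: int | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"unknown compartment {self.compartment!r} for {self.sample_id}"
            )
        if self.antigen not in ANTIGENS:
            raise ValidationError(f"unknown antigen {self.antigen!r} for {self.sample_id}")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"unknown timepoint {self.timepoint!r} for {self.sample_id}"
            )
        if self.compartment == "sorted_specific" and self.antigen == "none":
            raise ValidationError(
                f"sorted_specific sample {self.sample_id} must declare an antigen"
            )


def _resolve_columns(df: pd.DataFrame, column_map: dict | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    mandatory = ["rearrangement", "templates"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    if "productive" not in df.columns:
        if "frame_type" in df.columns:
            df = df.assign(productive=df["frame_type"].astype(str).str.strip() == "In")
        else:
            raise FormatError("missing mandatory column(s): productive (or frame_type)")
    if "amino_acid" not in df.columns:
        df = df.assign(amino_acid="")
    return df


def read_repertoire_tsv(
    path: str | Path,
    sample_id: str | None = None,
    total_nucleated_cells: int | None = None,
    column_map: dict | None = None,
) -> RepertoireSample:
    """Read a clone-level rearrangement table into a :class:`RepertoireSample`.

    Productive frequencies are always (re)computed over productive templates,
    so a file without a frequency column — or with a stale one — yields a
    consistent sample. Row order and the nucleotide rearrangement key are
    preserved.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    df = _resolve_columns(df, column_map)
    if (df["templates"] < 0).any():
        raise ValidationError(f"{path.name}: negative template count")
    return RepertoireSample(
        sample_id=sample_id or path.stem,
        clonotypes=df,
        total_nucleated_cells=total_nucleated_cells,
    )


def write_repertoire_tsv(sample: RepertoireSample, path: str | Path) -> None:
    """Write the clonotype table; template counts round-trip exactly."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    sample.clonotypes.to_csv(path, sep=sep, index=False)


MANIFEST_COLUMNS = ["sample_id", "subject_id", "compartment", "antigen", "timepoint", "file_path"]


def read_manifest(path: str | Path) -> list[SampleManifestEntry]:
    """Read and validate a sample manifest CSV.

    Rejects duplicate sample ids and unknown compartment/antigen/timepoint
    labels. An optional ``total_nucleated_cells`` column supplies the
    denominator for the T-cell fraction.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing column(s): {', '.join(missing)}")
    dupes = df["sample_id"][df["sample_id"].duplicated()]
    if len(dupes):
        raise ValidationError(f"duplicate sample_id(s): {sorted(set(dupes))}")
    entries = []
    for row in df.itertuples(index=False):
        tnc = getattr(row, "total_nucleated_cells", None)
        tnc = None if tnc is None or pd.isna(tnc) else int(tnc)
        entries.append(
            SampleManifestEntry(
                sample_id=str(row.sample_id),
                subject_id=str(row.subject_id),
                compartment=str(row.compartment),
                antigen=str(row.antigen),
                timepoint=str(row.timepoint),
                file_path=str(row.file_path),
                total_nucleated_cells=tnc,
            )
        )
    return entries


def write_manifest(entries: list[SampleManifestEntry], path: str | Path) -> None:
    pd.DataFrame([vars(e) for e in entries]).to_csv(path, index=False)


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Named, order-independent random stream derived from one master seed.

    Each (seed, stream-name) pair maps to its own ``SeedSequence`` spawn key
    via a CRC of the name, so adding a new generator elsewhere never perturbs
    existing streams and identical seeds reproduce identical bytes.
    """
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def get_logger(name: str = "immunotrack") -> logging.Logger:
    """Package logger writing timestamped lines to standard error."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger
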