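"""File formats: droplet CSV, sample sheet CSV, truth/results TSV, FASTA.

Droplet CSV is long format, one row per droplet, header exactly
``well_id,sample_id,assay_id,amplitude`` — streamable, diff-able, and
language-neutral.  The sample sheet carries per-extraction metadata with
header ``sample_id,subject_id,collection_day,stool_mass_mg,dilution_factor,
extraction_replicate,is_ntc,buffer,bristol,elution_volume_ul``; empty cells
are allowed only for optional fields (and mass for NTCs).
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .droplet import DropletWell
from .stats import SampleRecord

PathLike = Union[str, Path]

DROPLET_HEADER = ["well_id", "sample_id", "assay_id", "amplitude"]
SHEET_HEADER = [
    "sample_id", "subject_id", "collection_day", "stool_mass_mg",
    "dilution_factor", "extraction_replicate", "is_ntc", "buffer",
    "bristol", "elution_volume_ul",
]


class ParseError(ValueError):
    """Raised when an input file fails validation; message carries line numbers."""


def write_droplet_csv(wells: Iterable[DropletWell], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DROPLET_HEADER)
        for w in wells:
            for amp in w.amplitudes:
                writer.writerow([w.well_id, w.sample_id, w.assay_id, f"{amp:.4f}"])


def read_droplet_csv(path: PathLike) -> list[DropletWell]:
    """Read a droplet CSV into wells grouped by (well_id, sample_id, assay_id).

    The result is independent of row order: droplets are grouped by well and
    wells returned sorted by identity.  A well_id appearing with more than one
    (sample, assay) combination is an error — one well holds one reaction.
    """
    groups: dict[tuple[str, str, str], list[float]] = {}
    well_keys: dict[str, tuple[str, str, str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != DROPLET_HEADER:
            raise ParseError(
                f"{path}: expected header {','.join(DROPLET_HEADER)!r}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
            well_id, sample_id, assay_id, amp_str = row
            try:
                amp = float(amp_str)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric amplitude {amp_str!r}") from None
            if not np.isfinite(amp):
                raise ParseError(f"{path}:{lineno}: non-finite amplitude {amp_str!r}")
            key = (well_id, sample_id, assay_id)
            prev = well_keys.setdefault(well_id, key)
            if prev != key:
                raise ParseError(
                    f"{path}:{lineno}: well {well_id!r} mixes sample/assay "
                    f"{key[1:]} with {prev[1:]}"
                )
            groups.setdefault(key, []).append(amp)
    return [
        DropletWell(w, s, a, np.array(amps, dtype=float))
        for (w, s, a), amps in sorted(groups.items())
    ]


def _opt(value: str, cast, default=None):
    return default if value == "" else cast(value)


def write_sample_sheet(samples: Iterable[SampleRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SHEET_HEADER)
        for s in samples:
            writer.writerow([
                s.sample_id, s.subject_id, s.collection_day,
                "" if s.stool_mass_mg is None else repr(float(s.stool_mass_mg)),
                repr(float(s.dilution_factor)), s.extraction_replicate,
                str(s.is_ntc).lower(), s.buffer,
                "" if s.bristol is None else s.bristol,
                repr(float(s.elution_volume_ul)),
            ])


def read_sample_sheet(path: PathLike) -> list[SampleRecord]:
    """Read and validate a sample sheet; all violations reported together."""
    records: list[SampleRecord] = []
    errors: list[str] = []
    seen: set[tuple[str, int]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != SHEET_HEADER:
            raise ParseError(
                f"{path}: expected header {','.join(SHEET_HEADER)!r}, got {reader.fieldnames!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = SampleRecord(
                    sample_id=row["sample_id"],
                    subject_id=row["subject_id"],
                    collection_day=_opt(row["collection_day"], int, 0),
                    stool_mass_mg=_opt(row["stool_mass_mg"], float),
                    dilution_factor=_opt(row["dilution_factor"], float, 1.0),
                    extraction_replicate=_opt(row["extraction_replicate"], int, 1),
                    is_ntc=row["is_ntc"].strip().lower() in {"true", "1", "yes"},
                    buffer=row["buffer"] or "none",
                    bristol=_opt(row["bristol"], int),
                    elution_volume_ul=_opt(row["elution_volume_ul"], float, 100.0),
                )
            except (ValueError, KeyError) as exc:
                errors.append(f"{path}:{lineno}: {exc}")
                continue
            key = (rec.sample_id, rec.extraction_replicate)
            if key in seen:
                errors.append(
                    f"{path}:{lineno}: duplicate (sample_id, extraction_replicate) {key}"
                )
            seen.add(key)
            records.append(rec)
    if errors:
        raise ParseError("; ".join(errors))
    return records


def write_truth_tsv(truth: pd.DataFrame, path: PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """Read a (multi-record) FASTA into (id, uppercase sequence) pairs."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def sha256_of(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: PathLike, config: dict, inputs: dict[str, PathLike]) -> None:
    """Write a reproducibility sidecar: config echo plus input checksums."""
    manifest = {
        "config": config,
        "inputs": {name: {"path": str(p), "sha256": sha256_of(p)} for name, p in inputs.items()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
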