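"""Readers and writers for the external artifact formats.

Formats (all plain text):

* protein FASTA — sequences uppercased on read, a single trailing ``*`` stop
  symbol stripped, duplicate ids rejected; written wrapped at 60 columns.
* domain table — TSV with header ``protein_id source accession name start end``;
  1-based inclusive coordinates.
* features table — TSV ``protein_id signal_peptide(Y/N) tm_count``.
* phospho table — TSV ``protein_id position residue probability``.
* evidence table — CSV ``protein_id,extract_id,peptide_count``.
* lectin plate — CSV: first column the lectin name (one reserved row named
  ``BACKGROUND`` holds the no-lectin control), remaining columns replicate
  A405 readings.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ella import LectinPlate
from .model import (
    CANONICAL_EXTRACTS,
    DomainHit,
    EvidenceTable,
    FeatureFlags,
    PhosphoSite,
    PhosphoTrack,
    ProteinRecord,
    ShellomeError,
    unique_ids,
)

logger = logging.getLogger("shellome")

BACKGROUND_ROW = "BACKGROUND"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    path = Path(path)
    records: list[ProteinRecord] = []
    for sr in SeqIO.parse(str(path), "fasta"):
        seq = str(sr.seq).upper()
        if seq.endswith("*"):  # stop symbol: stripped from the end only
            seq = seq[:-1]
        records.append(ProteinRecord(id=sr.id, sequence=seq, description=sr.description[len(sr.id):].strip()))
    if not records:
        raise ShellomeError(f"{path}: no records")
    unique_ids(records)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecords)


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------

def _row_error(path: Path, lineno: int, msg: str) -> ShellomeError:
    return ShellomeError(f"{path}:{lineno}: {msg}")


def read_domain_table(path: str | Path) -> list[DomainHit]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["protein_id", "source", "accession", "name", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ShellomeError(f"{path}: missing columns {missing}")
    hits: list[DomainHit] = []
    for i, row in df.iterrows():
        lineno = int(i) + 2  # header is line 1
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError):
            raise _row_error(path, lineno, f"non-integer coordinates "
                             f"({row['start']!r}, {row['end']!r})") from None
        try:
            hits.append(DomainHit(
                protein_id=row["protein_id"], source=row["source"],
                accession=row["accession"],
                name=row["name"] if pd.notna(row["name"]) else "",
                start=start, end=end,
            ))
        except ShellomeError as exc:
            raise _row_error(path, lineno, str(exc)) from None
    return hits


def read_features_table(path: str | Path) -> list[FeatureFlags]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    flags: list[FeatureFlags] = []
    for i, row in df.iterrows():
        lineno = int(i) + 2
        sp = str(row["signal_peptide"]).strip().upper()
        if sp not in ("Y", "N", "YES", "NO"):
            raise _row_error(path, lineno, f"signal_peptide must be Y/N, got {sp!r}")
        try:
            tm = int(row["tm_count"])
        except (TypeError, ValueError):
            raise _row_error(path, lineno, f"non-integer tm_count {row['tm_count']!r}") from None
        try:
            flags.append(FeatureFlags(row["protein_id"], sp.startswith("Y"), tm))
        except ShellomeError as exc:
            raise _row_error(path, lineno, str(exc)) from None
    return flags


def read_phospho_table(path: str | Path) -> list[PhosphoTrack]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    by_protein: dict[str, list[PhosphoSite]] = {}
    for i, row in df.iterrows():
        lineno = int(i) + 2
        try:
            pos = int(row["position"])
            prob = float(row["probability"])
        except (TypeError, ValueError):
            raise _row_error(path, lineno, "non-numeric position/probability") from None
        try:
            site = PhosphoSite(pos, str(row["residue"]).strip().upper(), prob)
        except ShellomeError as exc:
            raise _row_error(path, lineno, str(exc)) from None
        by_protein.setdefault(row["protein_id"], []).append(site)
    tracks = []
    for pid, sites in by_protein.items():
        sites.sort(key=lambda s: s.position)
        tracks.append(PhosphoTrack(pid, tuple(sites)))
    return tracks


def read_evidence_table(
    path: str | Path,
    extract_ids: Sequence[str] = CANONICAL_EXTRACTS,
) -> EvidenceTable:
    path = Path(path)
    entries: dict[tuple[str, str], int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                count = int(row["peptide_count"])
            except (TypeError, ValueError):
                raise _row_error(path, lineno,
                                 f"non-integer peptide_count {row.get('peptide_count')!r}") from None
            if count < 0:
                raise _row_error(path, lineno, f"negative peptide count {count}")
            ext = row["extract_id"]
            if ext not in extract_ids:
                logger.warning("%s:%d: unknown extract id %r (preserved)", path, lineno, ext)
            entries[(row["protein_id"], ext)] = count
    return EvidenceTable(entries=entries, extract_ids=tuple(extract_ids))


def read_plate_csv(path: str | Path) -> LectinPlate:
    path = Path(path)
    df = pd.read_csv(path)
    name_col = df.columns[0]
    lectins: list[str] = []
    absorbance: dict[str, list[float]] = {}
    background: list[float] | None = None
    for i, row in df.iterrows():
        lineno = int(i) + 2
        name = str(row[name_col]).strip()
        readings = [float(v) for v in row.iloc[1:] if pd.notna(v)]
        if any(v < 0 for v in readings):
            raise _row_error(path, lineno, "negative absorbance reading")
        if name == BACKGROUND_ROW:
            background = readings
        else:
            lectins.append(name)
            absorbance[name] = readings
    if background is None:
        raise ShellomeError(f"{path}: background required (no {BACKGROUND_ROW!r} row)")
    return LectinPlate(lectins=tuple(lectins), absorbance=absorbance, background=tuple(background))


def write_plate_csv(plate: LectinPlate, path: str | Path) -> None:
    n_rep = max(len(v) for v in plate.absorbance.values())
    n_rep = max(n_rep, len(plate.background))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["lectin"] + [f"rep{i + 1}" for i in range(n_rep)])
        for lectin in plate.lectins:
            writer.writerow([lectin] + list(plate.absorbance[lectin]))
        writer.writerow([BACKGROUND_ROW] + list(plate.background))
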