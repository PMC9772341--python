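"""Sequence, alignment and table I/O plus the shared sequence data model.

Protein sequences are held as :class:`SequenceRecord` objects over the 20
canonical one-letter residue codes.  The ambiguity codes B, Z, X, U, O are
accepted on input but flagged as ambiguous; downstream composition features
exclude them from denominators.  Optional per-sequence annotations (signal
peptide boundary, optimal growth temperature, source database tag, activity
label/value) are serialized as ``KEY=value`` tokens in the FASTA description
line so that a FASTA file round-trips the full record.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO

from .errors import (
    AlignmentShapeError,
    ConfigError,
    DegenerateInputError,
    DuplicateIdError,
    FormatError,
)

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "BZXUO"
ACCEPTED_AA = CANONICAL_AA + AMBIGUOUS_AA
GAP_CHARS = "-."

_TOKEN_RE = re.compile(r"^(SP|OGT|SRC|ACT|ACTV)=(\S+)$")


@dataclass
class SequenceRecord:
    """One protein sequence with optional mining annotations.

    ``signal_peptide_end`` is the 1-based inclusive index of the last
    signal-peptide residue; ``ogt`` is the optimal growth temperature of the
    source organism/sample in degrees Celsius.
    """

    id: str
    residues: str
    description: str = ""
    signal_peptide_end: int | None = None
    ogt: float | None = None
    source: str | None = None
    activity_label: str | None = None  # "active" | "inactive"
    activity_value: float | None = None

    def __post_init__(self):
        self.residues = self.residues.upper().rstrip("*")
        if not self.residues:
            raise DegenerateInputError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - set(ACCEPTED_AA)
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid residue characters {sorted(bad)}"
            )
        if self.signal_peptide_end is not None:
            if not (1 <= self.signal_peptide_end < len(self.residues)):
                raise FormatError(
                    f"record {self.id!r}: signal_peptide_end "
                    f"{self.signal_peptide_end} outside [1, {len(self.residues) - 1}]"
                )
        if self.activity_label not in (None, "active", "inactive"):
            raise FormatError(
                f"record {self.id!r}: activity_label must be active/inactive"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def mature_residues(self) -> str:
        """Residues after the signal peptide (whole sequence when absent)."""
        if self.signal_peptide_end is None:
            return self.residues
        return self.residues[self.signal_peptide_end:]

    def unambiguous(self) -> str:
        return "".join(c for c in self.residues if c in CANONICAL_AA)


class Alignment:
    """Ordered rows of equal aligned length, '-' as the only gap character."""

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        if len(ids) != len(rows):
            raise AlignmentShapeError("ids and rows differ in length")
        if not rows:
            raise AlignmentShapeError("empty alignment")
        rows = [r.upper().replace(".", "-") for r in rows]
        n = len(rows[0])
        ragged = [i for i, r in zip(ids, rows) if len(r) != n]
        if ragged:
            raise AlignmentShapeError(
                f"rows of unequal aligned length: {ragged}", ids=ragged
            )
        if n < 1:
            raise AlignmentShapeError("alignment has zero columns")
        _check_unique(ids)
        self.ids = list(ids)
        self.rows = list(rows)
        self.records = list(zip(self.ids, self.rows))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def subset(self, keep_ids: Iterable[str], drop_all_gap: bool = True) -> "Alignment":
        """Row subset in original order; optionally drop columns that became all-gap."""
        keep = set(keep_ids)
        ids = [i for i in self.ids if i in keep]
        rows = [r for i, r in zip(self.ids, self.rows) if i in keep]
        if not rows:
            raise AlignmentShapeError("subset selects no rows")
        if drop_all_gap:
            cols = [j for j in range(len(rows[0])) if any(r[j] != "-" for r in rows)]
            rows = ["".join(r[j] for j in cols) for r in rows]
        return Alignment(ids, rows)


class OGTTable(dict):
    """Mapping id -> optimal growth temperature (deg C)."""


def _check_unique(ids: Sequence[str]):
    seen = set()
    for i in ids:
        if i in seen:
            raise DuplicateIdError(f"duplicate id {i!r}")
        seen.add(i)


# --- FASTA ------------------------------------------------------------------

def _parse_description(desc: str):
    """Split a FASTA description into free text and structured annotations."""
    ann = {}
    free = []
    for tok in desc.split():
        m = _TOKEN_RE.match(tok)
        if not m:
            free.append(tok)
            continue
        key, val = m.groups()
        if key == "SP":
            m2 = re.match(r"^1\.\.(\d+)$", val)
            if not m2:
                raise FormatError(f"malformed SP token {tok!r} (expected SP=1..N)")
            ann["signal_peptide_end"] = int(m2.group(1))
        elif key == "OGT":
            ann["ogt"] = float(val)
        elif key == "SRC":
            ann["source"] = val
        elif key == "ACT":
            ann["activity_label"] = val
        elif key == "ACTV":
            ann["activity_value"] = float(val)
    return " ".join(free), ann


def _format_description(rec: SequenceRecord) -> str:
    parts = [rec.description] if rec.description else []
    if rec.signal_peptide_end is not None:
        parts.append(f"SP=1..{rec.signal_peptide_end}")
    if rec.ogt is not None:
        parts.append(f"OGT={rec.ogt:g}")
    if rec.source is not None:
        parts.append(f"SRC={rec.source}")
    if rec.activity_label is not None:
        parts.append(f"ACT={rec.activity_label}")
    if rec.activity_value is not None:
        parts.append(f"ACTV={rec.activity_value:g}")
    return " ".join(parts)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (order preserved, ids unique).

    Residues are uppercased and a trailing '*' stop is stripped.  An empty
    file yields an empty list.  Structured ``KEY=value`` description tokens
    written by :func:`write_fasta` are recovered into record fields.
    """
    records = []
    try:
        for entry in SeqIO.parse(str(path), "fasta"):
            desc = entry.description
            if desc.startswith(entry.id):
                desc = desc[len(entry.id):].strip()
            free, ann = _parse_description(desc)
            records.append(
                SequenceRecord(id=entry.id, residues=str(entry.seq),
                               description=free, **ann)
            )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    _check_unique([r.id for r in records])
    # SeqIO silently skips junk before the first '>'; reject files with
    # non-empty content but no parsed entries.
    if not records:
        with open(path) as fh:
            stripped = fh.read().strip()
        if stripped:
            raise FormatError(f"{path}: no FASTA entries parsed from non-empty file")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60):
    with open(path, "w") as fh:
        for rec in records:
            desc = _format_description(rec)
            header = f">{rec.id} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# --- Alignments -------------------------------------------------------------

def read_alignment(path, dialect: str = "aligned-fasta") -> Alignment:
    """Read an MSA from aligned FASTA or Stockholm; '.' gaps normalized to '-'."""
    fmt = {"aligned-fasta": "fasta", "stockholm": "stockholm"}.get(dialect)
    if fmt is None:
        raise ConfigError(f"unknown alignment dialect {dialect!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        # Biopython raises ValueError on ragged rows; surface the offending ids.
        ids, rows = _raw_rows(path, fmt)
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            n = len(rows[0])
            bad = [i for i, r in zip(ids, rows) if len(r) != n]
            raise AlignmentShapeError(
                f"{path}: rows of unequal aligned length: {bad}", ids=bad
            ) from exc
        raise FormatError(f"{path}: {exc}") from exc
    return Alignment([r.id for r in msa], [str(r.seq) for r in msa])


def _raw_rows(path, fmt):
    if fmt == "fasta":
        ids, rows = [], []
        cur = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    ids.append(line[1:].split()[0] if len(line) > 1 else "")
                    rows.append("")
                    cur = len(rows) - 1
                elif line and cur is not None:
                    rows[cur] += line
        return ids, rows
    ids, rows = [], []
    order = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "//")):
                continue
            parts = line.split()
            if len(parts) != 2:
                continue
            name, seq = parts
            if name not in order:
                order[name] = len(ids)
                ids.append(name)
                rows.append("")
            rows[order[name]] += seq
    return ids, rows


def write_alignment(aln: Alignment, path, dialect: str = "aligned-fasta"):
    if dialect == "aligned-fasta":
        with open(path, "w") as fh:
            for i, row in zip(aln.ids, aln.rows):
                fh.write(f">{i}\n{row}\n")
    elif dialect == "stockholm":
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            for i, row in zip(aln.ids, aln.rows):
                fh.write(f"{i} {row}\n")
            fh.write("//\n")
    else:
        raise ConfigError(f"unknown alignment dialect {dialect!r}")


# --- Tables -----------------------------------------------------------------

def read_ogt_table(path) -> OGTTable:
    """Read a TSV with header columns ``id`` and ``ogt_celsius``."""
    table = OGTTable()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"id", "ogt_celsius"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: missing required columns id, ogt_celsius")
        for rownum, row in enumerate(reader, start=2):
            key = row["id"]
            try:
                val = float(row["ogt_celsius"])
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: row {rownum}: non-numeric temperature {row['ogt_celsius']!r}"
                )
            if val != val or val in (float("inf"), float("-inf")):
                raise FormatError(f"{path}: row {rownum}: non-finite temperature")
            if key in table:
                raise DuplicateIdError(f"{path}: row {rownum}: duplicate id {key!r}")
            table[key] = val
    return table


def read_label_table(path) -> dict:
    """Read a TSV with columns ``id``, ``label`` and optional ``activity``."""
    out = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"id", "label"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: missing required columns id, label")
        for rownum, row in enumerate(reader, start=2):
            if row["id"] in out:
                raise DuplicateIdError(f"{path}: row {rownum}: duplicate id {row['id']!r}")
            activity = row.get("activity")
            out[row["id"]] = (
                row["label"],
                float(activity) if activity not in (None, "") else None,
            )
    return out


def write_table(rows: Iterable[dict], path, columns: Sequence[str] | None = None):
    """Write dict rows as a TSV with a header; column order is fixed."""
    rows = list(rows)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns), delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def attach_ogt(records: Iterable[SequenceRecord], table: OGTTable) -> list[SequenceRecord]:
    """Return copies of records with ``ogt`` filled from the table where mapped."""
    return [
        replace(r, ogt=table[r.id]) if r.id in table else r for r in records
    ]
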