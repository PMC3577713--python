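"""Readers and writers for the delimited formats the pipeline touches.

Peak tables are flat delimited exports from fragment-analysis software
(one detected fragment per row); sequences are plain FASTA; binned
fingerprint matrices round-trip through labelled delimited text.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PeakRecord",
    "SequenceRecord",
    "PeakTableError",
    "FastaError",
    "read_peak_table",
    "read_fasta",
    "write_fasta",
    "write_matrix",
    "read_matrix",
    "format_bin_label",
]

PEAK_TABLE_COLUMNS = (
    "sample_id",
    "site",
    "season",
    "replicate_run",
    "enzyme",
    "size_bp",
    "area",
)

VALID_RESIDUES = frozenset("ACGTN")


class PeakTableError(ValueError):
    """Malformed peak table (missing column or bad row values)."""


class FastaError(ValueError):
    """Malformed FASTA input."""


@dataclass(frozen=True)
class PeakRecord:
    """One detected fragment in one capillary run of one sample."""

    sample_id: str
    site: str
    season: str
    replicate_run: int
    enzyme: str
    size_bp: float
    area: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicate_run", int(self.replicate_run))
        object.__setattr__(self, "size_bp", float(self.size_bp))
        object.__setattr__(self, "area", float(self.area))
        if self.size_bp <= 0:
            raise ValueError(f"size_bp must be > 0, got {self.size_bp}")
        if self.area <= 0:
            raise ValueError(f"area must be > 0, got {self.area}")
        if self.replicate_run not in (1, 2):
            raise ValueError(
                f"replicate_run must be 1 or 2, got {self.replicate_run}"
            )


@dataclass(frozen=True)
class SequenceRecord:
    """A 16S rDNA clone sequence attached to its library."""

    seq_id: str
    residues: str
    library_id: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for id {self.seq_id!r}")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.seq_id!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def _sniff_delimiter(header_line: str) -> str:
    # exports vary between tab and comma; the header decides
    if "\t" in header_line:
        return "\t"
    return ","


def read_peak_table(
    path: str | Path, dialect: str = "auto"
) -> list[PeakRecord]:
    """Read a delimited peak table into :class:`PeakRecord` rows.

    Parameters
    ----------
    path:
        Delimited text file with header naming the columns
        ``sample_id, site, season, replicate_run, enzyme, size_bp, area``.
    dialect:
        ``"tab"``, ``"comma"`` or ``"auto"`` (sniff from the header).

    Raises
    ------
    PeakTableError
        If a required column is missing, or any row has non-numeric
        size/area (the error message cites the 1-based data row number).
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines:
        raise PeakTableError(f"{path}: empty file, expected a header row")
    if dialect == "auto":
        delim = _sniff_delimiter(lines[0])
    elif dialect == "tab":
        delim = "\t"
    elif dialect == "comma":
        delim = ","
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    reader = csv.DictReader(lines, delimiter=delim)
    header = [h.strip() for h in (reader.fieldnames or [])]
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in header]
    if missing:
        raise PeakTableError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )

    records: list[PeakRecord] = []
    errors: list[str] = []
    for i, row in enumerate(reader, start=1):
        try:
            records.append(
                PeakRecord(
                    sample_id=row["sample_id"].strip(),
                    site=row["site"].strip(),
                    season=row["season"].strip(),
                    replicate_run=int(row["replicate_run"]),
                    enzyme=row["enzyme"].strip(),
                    size_bp=float(row["size_bp"]),
                    area=float(row["area"]),
                )
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise PeakTableError(
            f"{path}: {len(errors)} malformed row(s): " + "; ".join(errors)
        )
    return records


def write_peak_table(
    records: Iterable[PeakRecord], path: str | Path, delimiter: str = ","
) -> None:
    """Write records back out in the canonical column order."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(PEAK_TABLE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.sample_id,
                    r.site,
                    r.season,
                    r.replicate_run,
                    r.enzyme,
                    repr(r.size_bp),
                    repr(r.area),
                ]
            )


def read_fasta(path: str | Path, library_id: str = "") -> list[SequenceRecord]:
    """Read FASTA; ids are the first whitespace token of each header.

    Lowercase residues are upper-cased. Duplicate ids, empty sequences
    and sequence data before the first header raise :class:`FastaError`.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    seq_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if seq_id is None:
            return
        residues = "".join(chunks).upper()
        if not residues:
            raise FastaError(f"{path}: empty sequence for id {seq_id!r}")
        try:
            records.append(SequenceRecord(seq_id, residues, library_id))
        except ValueError as exc:
            raise FastaError(f"{path}: {exc}") from exc

    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                seq_id = line[1:].split()[0] if line[1:].split() else ""
                if not seq_id:
                    raise FastaError(f"{path}: header with empty id")
                if seq_id in seen:
                    raise FastaError(f"{path}: duplicate sequence id {seq_id!r}")
                seen[seq_id] = 1
                chunks = []
            else:
                if seq_id is None:
                    raise FastaError(
                        f"{path}: sequence data before first '>' header"
                    )
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.residues), 70):
                fh.write(rec.residues[i : i + 70] + "\n")


def format_bin_label(center: float) -> str:
    """Fingerprint bins are named by their size rounded to 0.1 bp."""
    return f"TRF-{center:.1f}"


def write_matrix(matrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write a binned fingerprint matrix as labelled delimited text.

    Rows are samples, columns are ``TRF-<size>`` bin labels; values keep
    6 significant digits so the matching reader round-trips losslessly
    at that precision.
    """
    df = pd.DataFrame(
        matrix.values,
        index=pd.Index(matrix.sample_ids, name="sample_id"),
        columns=[format_bin_label(c) for c in matrix.bin_centers],
    )
    df.to_csv(path, sep=delimiter, float_format="%.6g")


def read_matrix(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a matrix written by :func:`write_matrix` into a DataFrame."""
    return pd.read_csv(path, sep=delimiter, index_col=0)
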