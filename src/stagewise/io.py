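"""Readers and writers for all on-disk formats (TSV, FASTA/FASTQ, JSON).

Parsers reject malformed input rather than silently coercing it; writers
are byte-stable given identical inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from stagewise.design import ExperimentDesign
from stagewise.matrix import CountMatrix, ExpressionMatrix


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------- matrices


def read_count_matrix(path: str | Path, design: ExperimentDesign) -> CountMatrix:
    """Read a TSV count matrix (header = sample IDs, first column = features).

    Columns are reordered to ``design.samples``; a design sample missing from
    the file, a duplicate feature ID, or any non-integer/negative cell is an
    error naming the offending location.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing = [s for s in design.samples if s not in df.columns]
    if missing:
        raise ParseError(f"{path}: design samples missing from header: {missing}")
    df = df.loc[:, list(design.samples)]
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate feature ID {dup!r}")
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype="int64")
    for col in df.columns:
        for row, cell in df[col].items():
            try:
                value = int(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-integer cell {cell!r} at feature {row!r}, "
                    f"sample {col!r}"
                ) from None
            if value < 0:
                raise ParseError(
                    f"{path}: negative count {value} at feature {row!r}, "
                    f"sample {col!r}"
                )
            parsed.at[row, col] = value
    return CountMatrix(parsed, design)


def write_matrix(matrix: CountMatrix | ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with a ``feature_id`` index header."""
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_expression_matrix(
    path: str | Path, design: ExperimentDesign
) -> ExpressionMatrix:
    """Read a TSV of real-valued expression; same layout as count matrices."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [s for s in design.samples if s not in df.columns]
    if missing:
        raise ParseError(f"{path}: design samples missing from header: {missing}")
    return ExpressionMatrix(df.loc[:, list(design.samples)], design)


# ------------------------------------------------------------------ design


def read_design(path: str | Path) -> ExperimentDesign:
    """Read a two-column (sample_id, stage) design TSV.

    Stage order is the order of first appearance; transitions default to
    consecutive stage pairs.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "stage"]:
        raise ParseError(f"{path}: expected columns sample_id, stage")
    samples = tuple(df["sample_id"])
    stage_of = dict(zip(df["sample_id"], df["stage"]))
    stage_order = tuple(dict.fromkeys(df["stage"]))
    return ExperimentDesign(samples=samples, stage_of=stage_of, stage_order=stage_order)


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tstage\n")
        for s in design.samples:
            fh.write(f"{s}\t{design.stage_of[s]}\n")


# --------------------------------------------------------------- sequences

_VALID_SEQ = set("ACGTN")


def read_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ (auto-detected by leading character).

    Sequences are uppercased with U mapped to T; IDs are taken up to the
    first whitespace; qualities are discarded. An empty file yields an
    empty list.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1)
    if head == "":
        return []
    if head == ">":
        fmt = "fasta"
    elif head == "@":
        fmt = "fastq"
    else:
        raise ParseError(f"{path}: not FASTA or FASTQ (starts with {head!r})")
    records = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            seq = str(rec.seq).upper().replace("U", "T")
            if not set(seq) <= _VALID_SEQ:
                bad = sorted(set(seq) - _VALID_SEQ)
                raise ParseError(
                    f"{path}: record {rec.id!r} has invalid characters {bad}"
                )
            records.append((rec.id, seq))
    except ValueError as exc:  # Biopython structural errors
        raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write records as FASTQ with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ------------------------------------------------------------- hits tables


@dataclass(frozen=True)
class ContigHit:
    """One row of a 12-column tabular alignment (BLAST outfmt 6)."""

    contig_id: str
    cdna_id: str
    percent_identity: float
    length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")


def read_hits_table(path: str | Path) -> list[ContigHit]:
    """Parse a 12-column tab-separated alignment file, preserving row order."""
    hits: list[ContigHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                hit = ContigHit(
                    contig_id=fields[0],
                    cdna_id=fields[1],
                    percent_identity=float(fields[2]),
                    length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


# ----------------------------------------------------------- GO annotation


def read_go_table(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (feature_id, go_term) TSV into feature -> term set."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if lineno == 1 and line.startswith("feature_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            table.setdefault(fields[0], set()).add(fields[1])
    return table


def write_go_table(table: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tgo_term\n")
        for feature in sorted(table):
            for term in sorted(table[feature]):
                fh.write(f"{feature}\t{term}\n")


# -------------------------------------------------------------- pair table


def read_pairs_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column (srna_seq, transcript_id) TSV."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if lineno == 1 and line.startswith("srna_seq\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            pairs.append((fields[0], fields[1]))
    return pairs


def write_pairs_table(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("srna_seq\ttranscript_id\n")
        for seq, tid in pairs:
            fh.write(f"{seq}\t{tid}\n")


# ----------------------------------------------------------------- reports


def write_json_report(obj, path: str | Path) -> None:
    """Stable JSON: sorted keys, fixed separators, trailing newline."""

    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2, default=default)
        fh.write("\n")


def write_records_tsv(records, columns: list[str], path: str | Path, comment: str | None = None) -> None:
    """Write a list of dataclass-like records as TSV, one row per record."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            row = [str(getattr(rec, c)) for c in columns]
            fh.write("\t".join(row) + "\n")
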