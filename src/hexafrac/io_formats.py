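"""Reading, writing and rendering of the standard formats the pipeline touches.

FASTA and GFF3 carry the simulated (or real) genomic regions and their gene
models; report tables are rendered as TSV or JSON with a fixed per-column
rounding spec so that repeated runs are byte-stable.

Coordinate convention: every interval held in memory is 0-based half-open;
GFF3 on disk is 1-based inclusive.  The conversion is exact and involutive:
``[start, end)``  <->  ``(start + 1, end)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_DOWN, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("hexafrac")

# IUPAC nucleotide codes (uppercase) accepted in FASTA input.
_IUPAC_NT = set("ACGTURYSWKMBDHVN")


class FormatError(ValueError):
    """Raised for malformed FASTA/GFF3 input."""


def round_half_up(value: float, ndigits: int) -> float:
    """Round with ties away from zero (half-up), not banker's rounding.

    All printed percentages, densities, coverages and redundancies in the
    report tables use this rule; e.g. 8.65 -> 8.7 at one decimal.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def round_half_down(value: float, ndigits: int) -> float:
    """Round with ties toward zero.

    Used only for probe redundancy, whose published values resolve the
    .x5 tie downward (35/4 = 8.75 is reported as 8.7).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_DOWN))


def format_half_up(value: float, ndigits: int) -> str:
    """Render ``value`` half-up with exactly ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords.

    Sequences are uppercased (lowercase input is accepted and flagged in the
    log).  Duplicate ids, empty sequences and non-IUPAC characters raise
    :class:`FormatError` naming the offending record.  An empty file returns
    an empty list with a warning.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        log.warning("FASTA file %s contains no records", path)
        return []
    seen: set[str] = set()
    out: list[SeqRecord] = []
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"empty sequence for record {rec.id!r} in {path}")
        if seq != seq.upper():
            log.warning("record %s contains lowercase bases; uppercasing", rec.id)
            seq = seq.upper()
        bad = set(seq) - _IUPAC_NT
        if bad:
            raise FormatError(
                f"non-IUPAC characters {sorted(bad)} in record {rec.id!r} in {path}"
            )
        out.append(SeqRecord(Seq(seq), id=rec.id, description=""))
    return out


def write_fasta(records: Iterable[SeqRecord | tuple[str, str]],
                path: str | Path, wrap: int = 60) -> None:
    """Write records (SeqRecords or ``(id, sequence)`` pairs) as wrapped FASTA."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                rid, seq = rec
            else:
                rid, seq = rec.id, str(rec.seq)
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_STRANDS = {"+", "-"}
_FEATURE_TYPES = {"gene", "exon", "CDS", "TE", "insertion", "region"}


@dataclass
class Gff3Feature:
    """One GFF3 feature line; ``start``/``end`` are 1-based inclusive."""

    seqid: str
    source: str
    type: str
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)
    score: str = "."
    phase: str = "."

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"feature {self.attributes.get('ID', '?')}: "
                f"need 1 <= start <= end, got ({self.start}, {self.end})")
        if self.strand not in _STRANDS:
            raise FormatError(f"unknown strand {self.strand!r}")

    # -- coordinate conversion ------------------------------------------------
    @classmethod
    def from_interval(cls, seqid: str, type_: str, start0: int, end0: int,
                      strand: str, attributes: dict[str, str] | None = None,
                      source: str = "hexafrac") -> "Gff3Feature":
        """Build from a 0-based half-open interval ``[start0, end0)``."""
        return cls(seqid=seqid, source=source, type=type_,
                   start=start0 + 1, end=end0, strand=strand,
                   attributes=dict(attributes or {}))

    @property
    def interval(self) -> tuple[int, int]:
        """The feature's 0-based half-open interval."""
        return (self.start - 1, self.end)


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed attribute {part!r}")
        key, val = part.split("=", 1)
        attrs[key.strip()] = val.strip()
    return attrs


def read_gff3(path: str | Path, validate_parents: bool = True) -> list[Gff3Feature]:
    """Parse a 9-column GFF3 file; errors carry the 1-based line number."""
    path = Path(path)
    feats: list[Gff3Feature] = []
    ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, source, type_, start, end, score, strand, phase, attr = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end_i < start_i:
                raise FormatError(f"{path}:{lineno}: end {end_i} < start {start_i}")
            if strand not in _STRANDS:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = _parse_attributes(attr)
            fid = attrs.get("ID")
            if fid is not None:
                if fid in ids:
                    raise FormatError(f"{path}:{lineno}: duplicate ID {fid!r}")
                ids.add(fid)
            feats.append(Gff3Feature(seqid=seqid, source=source, type=type_,
                                     start=start_i, end=end_i, strand=strand,
                                     attributes=attrs, score=score, phase=phase))
    if validate_parents:
        for feat in feats:
            parent = feat.attributes.get("Parent")
            if parent is not None and parent not in ids:
                raise FormatError(
                    f"{path}: feature {feat.attributes.get('ID', '?')} "
                    f"references missing Parent {parent!r}")
    return feats


def write_gff3(features: Sequence[Gff3Feature], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attr = ";".join(f"{k}={v}" for k, v in f.attributes.items())
            fh.write("\t".join([f.seqid, f.source, f.type, str(f.start), str(f.end),
                                f.score, f.strand, f.phase, attr]) + "\n")


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

@dataclass
class ReportTable:
    """A named table with per-column rounding for byte-stable rendering.

    ``rounding`` maps column name -> number of decimals (half-up); columns not
    listed are rendered with ``str``.
    """

    name: str
    columns: list[str]
    rows: list[list[object]]
    rounding: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, row in enumerate(self.rows):
            if len(row) != len(self.columns):
                raise ValueError(
                    f"table {self.name}: row {i} has {len(row)} cells, "
                    f"expected {len(self.columns)}")

    def _render_cell(self, col: str, value: object) -> str:
        if col in self.rounding and isinstance(value, (int, float)):
            return format_half_up(float(value), self.rounding[col])
        return str(value)

    def render_rows(self) -> list[list[str]]:
        return [[self._render_cell(c, v) for c, v in zip(self.columns, row)]
                for row in self.rows]


def write_report(table: ReportTable, path: str | Path, format: str = "tsv") -> None:
    """Write a report as TSV or JSON; numbers follow the table's rounding spec."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rendered = table.render_rows()
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(table.columns) + "\n")
            for row in rendered:
                fh.write("\t".join(row) + "\n")
    elif format == "json":
        payload = {"name": table.name,
                   "columns": table.columns,
                   "rows": rendered}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
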