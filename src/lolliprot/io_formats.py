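"""Readers and writers for the tool's tabular inputs and aligned FASTA.

Three plain TSV formats (mutations, protein architecture, PTM sites) and
an aligned multi-FASTA carry everything the plotter needs.  Coordinates
are 1-based and intervals are inclusive on both ends, so a signal peptide
"from 1 to 24" starts at residue 1 and covers 24 residues.

Dialect rules shared by the TSV readers:

* fields are tab-separated;
* blank lines are skipped;
* lines starting with ``#`` are comments;
* a single optional header line is auto-detected -- if the position
  column of the first data line is not an integer and at least two more
  data lines follow, the line is treated as a header and skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: the 20 standard amino-acid letters
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
#: accepted reference residues: standard letters plus X (unknown)
REF_ALPHABET = frozenset(AA_LETTERS + "X")
#: accepted alternate residues: reference alphabet plus * (stop gained)
ALT_ALPHABET = frozenset(AA_LETTERS + "X*")


class ParseError(ValueError):
    """Malformed input file; the message names the file and line number."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationRecord:
    """One amino-acid change, e.g. C634R in RET.

    ``position`` is the 1-based residue index in the reference protein.
    ``ref_aa`` may be any standard letter or X; ``alt_aa`` additionally
    allows ``*`` for nonsense variants.
    """

    protein_name: str
    gene_name: str
    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_aa not in REF_ALPHABET:
            raise ValueError(f"invalid reference amino acid {self.ref_aa!r}")
        if self.alt_aa not in ALT_ALPHABET:
            raise ValueError(f"invalid alternate amino acid {self.alt_aa!r}")

    @property
    def label(self) -> str:
        """Conventional short label, e.g. ``C634R``."""
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class DomainAnnotation:
    """A named contiguous interval on the protein, inclusive on both ends."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("domain name must be non-empty")
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"domain {self.name!r}: need 1 <= start <= end, "
                f"got start={self.start}, end={self.end}"
            )

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class PTMSite:
    """A post-translationally modified residue position (1-based)."""

    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"PTM position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class ProteinContext:
    """Length of the plotted protein and the title shown on the figure."""

    length: int
    query_name: str

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"protein length must be >= 1, got {self.length}")


@dataclass
class AlignmentSet:
    """An aligned set of sequences with one designated reference row.

    ``records`` preserves file order; all aligned sequences share the
    same column count and use ``-`` as the only gap character.
    """

    records: list[tuple[str, str]]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no sequences")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        ids = [rid for rid, _ in self.records]
        if ids.count(self.reference_id) != 1:
            raise ValueError(
                f"reference id {self.reference_id!r} must match exactly one "
                f"record; available identifiers: {ids}"
            )

    @property
    def column_count(self) -> int:
        return len(self.records[0][1])

    @property
    def identifiers(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def reference_row(self) -> str:
        for rid, seq in self.records:
            if rid == self.reference_id:
                return seq
        raise AssertionError("unreachable: reference checked in __post_init__")

    def non_reference_rows(self) -> list[str]:
        return [seq for rid, seq in self.records if rid != self.reference_id]


# ---------------------------------------------------------------------------
# TSV line scaffolding
# ---------------------------------------------------------------------------

def _data_lines(path: PathLike) -> list[tuple[int, list[str]]]:
    """Return (1-based line number, tab-split fields) for each data line."""
    text = Path(path).read_text()
    out = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        out.append((lineno, line.split("\t")))
    return out


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def _strip_header(
    lines: list[tuple[int, list[str]]], position_column: int
) -> list[tuple[int, list[str]]]:
    """Drop a single leading header line when it is safely detectable.

    The first data line is taken as a header only when its position
    column is non-integer AND at least two data lines follow -- a
    one-line file with a bad position is a parse error, not a header.
    """
    if len(lines) >= 3:
        _, fields = lines[0]
        if len(fields) > position_column and not _is_int(fields[position_column]):
            return lines[1:]
    return lines


def _parse_position(token: str, path: PathLike, lineno: int, what: str) -> int:
    if not _is_int(token):
        raise ParseError(f"{path}, line {lineno}: non-integer {what} {token!r}")
    value = int(token)
    if value < 1:
        raise ParseError(f"{path}, line {lineno}: {what} {value} is < 1")
    return value


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_mutation_file(path: PathLike) -> list[MutationRecord]:
    """Parse a mutation TSV: protein, gene, position, ref, alt.

    Records are returned in file order with duplicates preserved;
    amino-acid letters are uppercased.  Synonymous entries (ref == alt)
    are skipped with a warning rather than aborting the batch.
    """
    lines = _strip_header(_data_lines(path), position_column=2)
    if not lines:
        raise ParseError(f"{path}: no mutation records found")
    records: list[MutationRecord] = []
    for lineno, fields in lines:
        if len(fields) < 5:
            raise ParseError(
                f"{path}, line {lineno}: expected >= 5 tab-separated fields "
                f"(protein, gene, position, ref, alt), got {len(fields)}"
            )
        protein, gene = fields[0].strip(), fields[1].strip()
        position = _parse_position(fields[2].strip(), path, lineno, "position")
        ref_aa, alt_aa = fields[3].strip().upper(), fields[4].strip().upper()
        for role, aa, alphabet in (
            ("reference", ref_aa, REF_ALPHABET),
            ("alternate", alt_aa, ALT_ALPHABET),
        ):
            if len(aa) != 1 or aa not in alphabet:
                raise ParseError(
                    f"{path}, line {lineno}: invalid {role} amino acid {aa!r}"
                )
        if ref_aa == alt_aa:
            logger.warning(
                "%s, line %d: synonymous entry %s%d%s skipped",
                path, lineno, ref_aa, position, alt_aa,
            )
            continue
        records.append(MutationRecord(protein, gene, position, ref_aa, alt_aa))
    if not records:
        raise ParseError(f"{path}: no mutation records found")
    return records


def read_architecture_file(path: PathLike) -> list[DomainAnnotation]:
    """Parse a protein-architecture TSV: name, start, end (both inclusive)."""
    lines = _strip_header(_data_lines(path), position_column=1)
    domains: list[DomainAnnotation] = []
    for lineno, fields in lines:
        if len(fields) < 3:
            raise ParseError(
                f"{path}, line {lineno}: expected >= 3 tab-separated fields "
                f"(name, start, end), got {len(fields)}"
            )
        name = fields[0].strip()
        if not name:
            raise ParseError(f"{path}, line {lineno}: empty domain name")
        start = _parse_position(fields[1].strip(), path, lineno, "start")
        end = _parse_position(fields[2].strip(), path, lineno, "end")
        if start > end:
            raise ParseError(
                f"{path}, line {lineno}: domain {name!r} start exceeds end "
                f"({start} > {end})"
            )
        domains.append(DomainAnnotation(name, start, end))
    return domains


def read_ptm_file(path: PathLike) -> list[PTMSite]:
    """Parse a PTM TSV: one site position per line (first field).

    An empty file yields an empty list; the PTM track is simply omitted
    downstream.  Duplicates are preserved in file order.
    """
    lines = _strip_header(_data_lines(path), position_column=0)
    return [
        PTMSite(_parse_position(fields[0].strip(), path, lineno, "PTM position"))
        for lineno, fields in lines
    ]


def read_alignment(path: PathLike, reference_id: str) -> AlignmentSet:
    """Read an aligned multi-FASTA (e.g. MUSCLE output).

    Sequences are uppercased; ``.`` gaps are normalised to ``-``.  The
    identifier is the first whitespace-delimited token of each header.
    Ragged alignments and missing reference identifiers raise with the
    offending/available identifiers named.
    """
    records = [
        (rec.id, str(rec.seq).upper().replace(".", "-"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    expected = len(records[0][1])
    for rid, seq in records:
        if len(seq) != expected:
            raise ParseError(
                f"{path}: ragged alignment -- sequence {rid!r} has length "
                f"{len(seq)}, expected {expected}"
            )
    ids = [rid for rid, _ in records]
    if reference_id not in ids:
        raise ParseError(
            f"{path}: reference id {reference_id!r} not found; available "
            f"identifiers: {ids}"
        )
    return AlignmentSet(records=records, reference_id=reference_id)


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers above)
# ---------------------------------------------------------------------------

def write_mutation_file(records: Iterable[MutationRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.protein_name}\t{r.gene_name}\t{r.position}\t{r.ref_aa}\t{r.alt_aa}\n"
            )


def write_architecture_file(domains: Iterable[DomainAnnotation], path: PathLike) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{d.name}\t{d.start}\t{d.end}\n")


def write_ptm_file(sites: Iterable[PTMSite], path: PathLike) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.position}\n")


def write_alignment(alignment: AlignmentSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for rid, seq in alignment.records:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# cross-input validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Out-of-range findings across all parsed inputs.

    Validation never raises; callers inspect the report and decide
    whether to abort.  The report is empty iff every position and
    interval fits inside the protein.
    """

    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.violations)

    @property
    def is_empty(self) -> bool:
        return not self.violations


def validate_inputs(
    mutations: Sequence[MutationRecord],
    domains: Sequence[DomainAnnotation],
    ptms: Sequence[PTMSite],
    context: ProteinContext,
) -> ValidationReport:
    """Check every position and interval against the protein length.

    Bounds are inclusive: a domain ending exactly at ``context.length``
    is in range.
    """
    report = ValidationReport()
    for i, m in enumerate(mutations):
        if not 1 <= m.position <= context.length:
            report.violations.append(
                f"mutation #{i + 1} ({m.label}): position {m.position} outside "
                f"1..{context.length}"
            )
    for d in domains:
        if d.end > context.length:
            report.violations.append(
                f"domain {d.name!r}: end {d.end} exceeds protein length "
                f"{context.length}"
            )
    for i, p in enumerate(ptms):
        if p.position > context.length:
            report.violations.append(
                f"PTM site #{i + 1}: position {p.position} exceeds protein "
                f"length {context.length}"
            )
    return report
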