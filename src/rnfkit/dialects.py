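"""Converters from other simulators' read-naming conventions.

Upstream simulators encode a read's true origin either in the read name
(wgsim, dwgsim, CuReSim — each with its own grammar and coordinate
semantics) or in a truth SAM file (Art/Mason style).  This module parses
those conventions and re-emits the reads as origin-named FASTQ.

Name grammars are data, not code: a :class:`DialectGrammar` bundles a
regular expression with named capture groups and a coordinate-semantics
flag.  Built-in grammars follow the widely documented upstream defaults
but can be overridden from a plain-text ``key=value`` pattern file, since
upstream formats drift between versions.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam

from . import io as rio
from .model import NamePolicy, Read, ReadTuple, RnfError, Segment, hex_width_for

__all__ = [
    "CoordinateSemantics",
    "DialectGrammar",
    "DialectParseError",
    "EndOrigin",
    "BUILTIN_GRAMMARS",
    "load_grammar_file",
    "parse_dialect_name",
    "convert_fastq",
    "convert_from_sam",
]


class CoordinateSemantics(enum.Enum):
    """How a captured position relates to the end's interval.

    ``LEFTMOST_EACH_END``: the captured position is the leftmost base of
    the end regardless of strand.  ``FIRST_NUCLEOTIDE_EACH_END``: the
    captured position is the first sequenced base, i.e. the leftmost base
    of a forward end but the rightmost base of a reverse end.
    """

    FIRST_NUCLEOTIDE_EACH_END = "first_nucleotide_each_end"
    LEFTMOST_EACH_END = "leftmost_each_end"


class DialectParseError(RnfError):
    pass


@dataclass(frozen=True)
class EndOrigin:
    """Per-end origin parsed from a dialect name (a Segment precursor)."""

    chrom: str
    direction: str
    left: int
    right: int


@dataclass(frozen=True)
class DialectGrammar:
    dialect_name: str
    name_pattern: str
    coordinate_semantics: CoordinateSemantics
    pairing_rule: str = "suffix"  # "suffix" (/1,/2) or "file"
    #: strand assumed for ends whose strand is not captured by the pattern
    default_strands: tuple[str, ...] = ()

    _compiled: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_compiled", re.compile(self.name_pattern))

    def match(self, name: str) -> re.Match:
        if self.pairing_rule == "suffix":
            name = re.sub(r"/[12]$", "", name)
        m = self._compiled.match(name)
        if not m:
            raise DialectParseError(
                f"name {name!r} does not match the {self.dialect_name} grammar"
            )
        return m


def _strand_char(raw: str | None) -> str:
    if raw is None:
        return "N"
    if raw in ("0", "+", "F", "f"):
        return "F"
    if raw in ("1", "-", "R", "r"):
        return "R"
    raise DialectParseError(f"unrecognized strand field {raw!r}")


BUILTIN_GRAMMARS: dict[str, DialectGrammar] = {
    # <chrom>_<pos1>_<pos2>_<e>:<s>:<i>_<e>:<s>:<i>_<counter>[/end]
    # positions are the first sequenced nucleotide of each end;
    # end 1 forward, end 2 reverse by convention (strand not encoded)
    "wgsim": DialectGrammar(
        dialect_name="wgsim",
        name_pattern=(
            r"^(?P<chrom>.+)_(?P<pos1>\d+)_(?P<pos2>\d+)"
            r"_\d+:\d+:\d+_\d+:\d+:\d+_(?P<counter>[0-9a-fA-F]+)$"
        ),
        coordinate_semantics=CoordinateSemantics.FIRST_NUCLEOTIDE_EACH_END,
        default_strands=("F", "R"),
    ),
    # <chrom>_<pos1>_<pos2>_<strand1>_<strand2>_<rand1>_<rand2>_<counter>[/end]
    # positions are the leftmost nucleotide of each end; strand 0/1
    "dwgsim": DialectGrammar(
        dialect_name="dwgsim",
        name_pattern=(
            r"^(?P<chrom>.+)_(?P<pos1>\d+)_(?P<pos2>\d+)"
            r"_(?P<strand1>[01])_(?P<strand2>[01])_[01]_[01]"
            r"_(?P<counter>[0-9a-fA-F]+)$"
        ),
        coordinate_semantics=CoordinateSemantics.LEFTMOST_EACH_END,
    ),
    # <chrom>_<pos>_<length>_<ndel>_<nins>_<nsub>_<counter>
    # single-end, leftmost nucleotide, strand not encoded
    "curesim": DialectGrammar(
        dialect_name="curesim",
        name_pattern=(
            r"^(?P<chrom>.+)_(?P<pos1>\d+)_\d+_\d+_\d+_\d+_(?P<counter>\d+)$"
        ),
        coordinate_semantics=CoordinateSemantics.LEFTMOST_EACH_END,
    ),
}


def load_grammar_file(path: str) -> DialectGrammar:
    """Load a grammar from a ``key=value`` pattern file.

    Recognized keys: ``name``, ``pattern``, ``semantics``
    (``leftmost_each_end`` / ``first_nucleotide_each_end``),
    ``pairing_rule`` and optional ``default_strands`` (comma-separated).
    """
    fields: dict[str, str] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise RnfError(f"{path}:{line_no}: expected key=value")
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
    missing = {"name", "pattern", "semantics"} - fields.keys()
    if missing:
        raise RnfError(f"{path}: missing keys {sorted(missing)}")
    return DialectGrammar(
        dialect_name=fields["name"],
        name_pattern=fields["pattern"],
        coordinate_semantics=CoordinateSemantics(fields["semantics"].lower()),
        pairing_rule=fields.get("pairing_rule", "suffix"),
        default_strands=tuple(
            s.strip() for s in fields.get("default_strands", "").split(",")
            if s.strip()
        ),
    )


def parse_dialect_name(
    name: str, grammar: DialectGrammar, read_length: int
) -> list[EndOrigin]:
    """Parse one dialect name into per-end origin intervals.

    Under leftmost semantics the captured position is ``left`` and
    ``right = left + read_length - 1`` when the strand is known (with an
    unknown strand the interval's right end cannot be trusted, so
    direction ``N`` and ``right = 0`` are emitted).  Under
    first-nucleotide semantics a forward end's position is its leftmost
    base while a reverse end's position is its rightmost base.
    """
    m = grammar.match(name)
    groups = m.groupdict()
    chrom = groups.get("chrom")
    if chrom is None:
        raise DialectParseError(
            f"{grammar.dialect_name} grammar captured no chromosome"
        )
    ends: list[EndOrigin] = []
    for end_index in (1, 2):
        pos_raw = groups.get(f"pos{end_index}")
        if pos_raw is None:
            continue
        pos = int(pos_raw)
        strand_raw = groups.get(f"strand{end_index}")
        if strand_raw is not None:
            direction = _strand_char(strand_raw)
        elif len(grammar.default_strands) >= end_index:
            direction = grammar.default_strands[end_index - 1]
        else:
            direction = "N"
        if grammar.coordinate_semantics is CoordinateSemantics.LEFTMOST_EACH_END:
            if direction == "N":
                left, right = pos, 0
            else:
                left, right = pos, pos + read_length - 1
        else:  # FIRST_NUCLEOTIDE_EACH_END
            if direction == "F":
                left, right = pos, pos + read_length - 1
            elif direction == "R":
                left, right = pos - read_length + 1, pos
            else:
                left, right = pos, 0
        ends.append(EndOrigin(chrom=chrom, direction=direction,
                              left=left, right=right))
    if not ends:
        raise DialectParseError(
            f"{grammar.dialect_name} grammar captured no position in {name!r}"
        )
    return ends


def _chrom_id(chrom: str, chrom_ids: dict[str, int], auto: bool) -> int:
    if chrom not in chrom_ids:
        if not auto:
            raise RnfError(f"unknown chromosome {chrom!r} (not in the chromosome map)")
        chrom_ids[chrom] = len(chrom_ids) + 1
    return chrom_ids[chrom]


def convert_fastq(
    input_paths: Sequence[str],
    output_paths: Sequence[str],
    grammar: DialectGrammar,
    genome_id: int = 1,
    chrom_ids: dict[str, int] | None = None,
    prefix: str = "",
) -> tuple[list[str], str]:
    """Convert dialect-named FASTQ file(s) into origin-named FASTQ.

    One input file means single-end (end 1 of the name is used); two
    files mean a read pair whose tuple combines both ends.  Tuple IDs
    are assigned sequentially in input order starting at 1.  When no
    chromosome map is given, IDs are assigned by order of first
    appearance.  The correspondence file is always written (possibly
    empty) next to the first output.
    """
    if len(input_paths) not in (1, 2) or len(output_paths) != len(input_paths):
        raise RnfError("expected 1 (single-end) or 2 (paired) input/output files")
    auto_map = chrom_ids is None
    chrom_ids = dict(chrom_ids) if chrom_ids else {}

    files = [list(rio.read_fastq(p)) for p in input_paths]
    counts = {len(f) for f in files}
    if len(counts) > 1:
        raise RnfError(f"paired inputs differ in record count: {sorted(counts)}")

    entries: list[tuple[ReadTuple, list[tuple[str, str]]]] = []
    for idx in range(len(files[0])):
        records = [f[idx] for f in files]
        name = records[0][0]
        reads: list[Read] = []
        for end_index, (_, seq, qual) in enumerate(records, start=1):
            try:
                ends = parse_dialect_name(name, grammar, len(seq))
            except DialectParseError as exc:
                raise DialectParseError(f"record {idx + 1}: {exc}") from exc
            origin = ends[end_index - 1] if len(ends) >= end_index else ends[0]
            seg = Segment(
                genome_id=genome_id,
                chromosome_id=_chrom_id(origin.chrom, chrom_ids, auto_map),
                direction=origin.direction,
                left=origin.left,
                right=origin.right,
            )
            reads.append(Read([seg]))
        entries.append((
            ReadTuple(tuple_id=idx + 1, reads=reads, prefix=prefix),
            [(seq, qual) for _, seq, qual in records],
        ))

    policy = NamePolicy(id_hex_width=hex_width_for(len(entries)))
    _, corr_path = rio.write_rnf_fastq(entries, output_paths, policy,
                                       always_correspondence=True)
    return list(output_paths), corr_path  # corr always written


def _cigar_reference_span(cigartuples: Iterable[tuple[int, int]]) -> int:
    # M/D/N/=/X consume reference
    return sum(length for op, length in cigartuples if op in (0, 2, 3, 7, 8))


def convert_from_sam(
    sam_path: str,
    output_paths: Sequence[str] | None = None,
    genome_id: int = 1,
    prefix: str = "",
) -> tuple[list[str], str]:
    """Convert a truth SAM file (Art/Mason style) into origin-named FASTQ.

    Records are grouped by QNAME; every primary record is one read, and
    secondary/supplementary records become additional segments of the
    read with the same end (chimeric truth).  Chromosome IDs follow the
    1-based order of ``@SQ`` headers.  All tuples must have the same
    number of reads (uniformly single-end or uniformly paired).
    """
    with pysam.AlignmentFile(sam_path, check_sq=False) as sam:
        refs = list(sam.references)
        if not refs:
            raise RnfError(f"{sam_path}: missing @SQ headers")
        chrom_ids = {name: i + 1 for i, name in enumerate(refs)}
        groups: dict[str, dict[int, dict]] = {}
        order: list[str] = []
        for rec in sam.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                is_primary = False
            else:
                is_primary = True
            end = 2 if rec.is_read2 else 1
            if rec.query_name not in groups:
                groups[rec.query_name] = {}
                order.append(rec.query_name)
            ends = groups[rec.query_name]
            slot = ends.setdefault(end, {"seq": None, "qual": None,
                                         "segments": []})
            if not rec.is_unmapped:
                if rec.cigartuples is None:
                    raise RnfError(
                        f"{sam_path}: mapped record {rec.query_name!r} has no CIGAR"
                    )
                left = rec.reference_start + 1
                right = left + _cigar_reference_span(rec.cigartuples) - 1
                slot["segments"].append(Segment(
                    genome_id=genome_id,
                    chromosome_id=chrom_ids[rec.reference_name],
                    direction="R" if rec.is_reverse else "F",
                    left=left,
                    right=right,
                ))
            elif not slot["segments"]:
                slot["segments"].append(
                    Segment(genome_id=genome_id, chromosome_id=0,
                            direction="N", left=0, right=0))
            if is_primary and rec.query_sequence is not None:
                seq = rec.query_sequence
                qual = (rec.qual if rec.qual is not None else "I" * len(seq))
                if rec.is_reverse:
                    seq = rio.revcomp(seq)
                    qual = qual[::-1]
                slot["seq"], slot["qual"] = seq, qual

    entries: list[tuple[ReadTuple, list[tuple[str, str]]]] = []
    n_reads_layout: int | None = None
    for tid, qname in enumerate(order, start=1):
        ends = groups[qname]
        reads, seqs = [], []
        for end in sorted(ends):
            slot = ends[end]
            if slot["seq"] is None:
                raise RnfError(
                    f"{sam_path}: no primary record with sequence for "
                    f"{qname!r} end {end}"
                )
            reads.append(Read(slot["segments"]))
            seqs.append((slot["seq"], slot["qual"]))
        if n_reads_layout is None:
            n_reads_layout = len(reads)
        elif n_reads_layout != len(reads):
            raise RnfError(
                f"{sam_path}: mixed single-end/paired truth layouts are not supported"
            )
        entries.append((ReadTuple(tuple_id=tid, reads=reads, prefix=prefix),
                        seqs))

    if output_paths is None:
        base = sam_path.rsplit(".", 1)[0]
        n = n_reads_layout or 1
        output_paths = ([f"{base}.fq"] if n == 1
                        else [f"{base}_{k}.fq" for k in range(1, n + 1)])
    policy = NamePolicy(id_hex_width=hex_width_for(len(entries)))
    if entries:
        _, corr = rio.write_rnf_fastq(entries, output_paths, policy,
                                      always_correspondence=True)
    else:
        for p in output_paths:
            rio.write_fastq(p, [])
        corr = rio.correspondence_path(output_paths[0])
        rio.write_correspondence(corr, [])
    return list(output_paths), corr
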