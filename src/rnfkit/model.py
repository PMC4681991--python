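"""Data model and canonical string codec for origin-encoded read names.

A read *tuple* is everything a sequencing machine produced from one DNA
fragment; each of its *reads* is a chain of one or more *segments*, one
segment per spatially distinct origin interval in the reference.  Every
tuple can be rendered as two names:

* a long read name (LRN) — four ``__``-delimited parts: prefix, hexadecimal
  tuple ID, the comma-joined sorted segment block, and a suffix holding
  ``[tag:value]`` extensions;
* a short read name (SRN) — ``#`` followed by the hexadecimal tuple ID,
  used as a fallback when the LRN would exceed the maximum name length
  (default 255 characters), in which case an SRN–LRN correspondence
  record must be written alongside the output.

Coordinates are 1-based and fully closed throughout; ``0`` means unknown
(direction ``N`` plays the same role for strand).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Segment",
    "Read",
    "ReadTuple",
    "NamePolicy",
    "RnfError",
    "ValidationError",
    "FormatError",
    "sort_segments",
    "encode_segment",
    "decode_segment",
    "encode_lrn",
    "decode_lrn",
    "encode_srn",
    "decode_srn",
    "choose_name",
    "validate_name",
    "hex_width_for",
    "assign_names",
]

DIRECTIONS = frozenset("FRN")

_PREFIX_RE = re.compile(r"^[A-Za-z0-9-]*$")
# direction captured loosely so a bad letter is reported as such, not as a
# generic pattern mismatch
_SEGMENT_RE = re.compile(r"\((\d+),(\d+),([A-Za-z]),(\d+),(\d+)\)")
_EXTENSION_RE = re.compile(r"\[([A-Za-z0-9]+):([^\[\]_]*)\]")
_SRN_RE = re.compile(r"^#([0-9a-f]+)$")
_HEX_RE = re.compile(r"^[0-9a-f]+$")
_TAG_RE = re.compile(r"^[A-Za-z0-9]+$")
_EXT_VALUE_RE = re.compile(r"^[^\[\]_]*$")


class RnfError(ValueError):
    """Base class for all naming-format errors."""


class ValidationError(RnfError):
    """A domain object violates one of its invariants."""


class FormatError(RnfError):
    """A name string does not parse under the grammar."""


@dataclass(frozen=True)
class Segment:
    """One spatially distinct origin interval of a read.

    ``genome_id``/``chromosome_id`` 0 mean "unknown"; coordinates are
    1-based closed with 0 for "unknown"; direction is ``F``, ``R`` or
    ``N`` (unknown).
    """

    genome_id: int = 0
    chromosome_id: int = 0
    direction: str = "N"
    left: int = 0
    right: int = 0

    def violations(self) -> list[str]:
        v = []
        if self.genome_id < 0:
            v.append(f"genome_id must be >= 0, got {self.genome_id}")
        if self.chromosome_id < 0:
            v.append(f"chromosome_id must be >= 0, got {self.chromosome_id}")
        if self.direction not in DIRECTIONS:
            v.append(f"invalid direction {self.direction!r}")
        if self.left < 0:
            v.append(f"left must be >= 0, got {self.left}")
        if self.right < 0:
            v.append(f"right must be >= 0, got {self.right}")
        if self.left > 0 and self.right > 0 and self.left > self.right:
            v.append(f"left > right ({self.left} > {self.right})")
        return v

    @property
    def sort_key(self) -> tuple:
        # F < N < R falls out of character-code order
        return (self.genome_id, self.chromosome_id, self.left, self.right,
                self.direction)


@dataclass
class Read:
    """One sequencing output of a tuple: an ordered chain of segments.

    ``chimeric=True`` asserts the read spans a fusion/translocation and
    therefore must carry at least two segments.
    """

    segments: list[Segment]
    chimeric: bool = False

    def violations(self) -> list[str]:
        v = []
        if not self.segments:
            v.append("read has no segments")
        if self.chimeric and len(self.segments) < 2:
            v.append("chimeric read must have at least two segments")
        for i, seg in enumerate(self.segments):
            v.extend(f"segment {i}: {msg}" for msg in seg.violations())
        return v


@dataclass
class ReadTuple:
    """A named tuple of reads obtained from a single DNA fragment."""

    tuple_id: int
    reads: list[Read]
    prefix: str = ""
    extensions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reads = [
            r if isinstance(r, Read) else Read(list(r)) for r in self.reads
        ]

    @property
    def segments(self) -> list[Segment]:
        """All segments of all reads, in read order (unsorted)."""
        return [s for read in self.reads for s in read.segments]

    def violations(self) -> list[str]:
        v = []
        if self.tuple_id < 1:
            v.append(f"tuple_id must be >= 1, got {self.tuple_id}")
        if "__" in self.prefix or not _PREFIX_RE.match(self.prefix):
            v.append(f"prefix must match [A-Za-z0-9-]*, got {self.prefix!r}")
        if not self.reads:
            v.append("tuple has no reads")
        for i, read in enumerate(self.reads):
            v.extend(f"read {i}: {msg}" for msg in read.violations())
        for tag, value in self.extensions:
            if not _TAG_RE.match(tag):
                v.append(f"extension tag must be alphanumeric, got {tag!r}")
            if not _EXT_VALUE_RE.match(value):
                v.append(
                    f"extension value must not contain '[', ']' or '_', got {value!r}"
                )
        return v

    def validate(self) -> None:
        v = self.violations()
        if v:
            raise ValidationError("; ".join(v))


@dataclass(frozen=True)
class NamePolicy:
    """How names are rendered: hex padding width and the LRN/SRN fallback."""

    id_hex_width: int = 1
    max_lrn_length: int = 255
    srn_fallback: bool = True

    def __post_init__(self) -> None:
        if self.id_hex_width < 1:
            raise ValidationError("id_hex_width must be >= 1")


def sort_segments(segments: Iterable[Segment]) -> list[Segment]:
    """Stable sort by (genome, chromosome, left, right, direction)."""
    return sorted(segments, key=lambda s: s.sort_key)


def encode_segment(segment: Segment, *, validate: bool = True) -> str:
    """Render one segment as ``(g,c,D,l,r)``."""
    if validate:
        v = segment.violations()
        if v:
            raise ValidationError("; ".join(v))
    return (f"({segment.genome_id},{segment.chromosome_id},"
            f"{segment.direction},{segment.left},{segment.right})")


def decode_segment(text: str) -> Segment:
    """Inverse of :func:`encode_segment` for a single segment string."""
    m = _SEGMENT_RE.fullmatch(text)
    if not m:
        raise FormatError(f"malformed segment {text!r}")
    seg = Segment(int(m[1]), int(m[2]), m[3], int(m[4]), int(m[5]))
    bad = seg.violations()
    if bad:
        raise FormatError("; ".join(bad))
    return seg


def encode_lrn(tuple_: ReadTuple, policy: NamePolicy | None = None) -> str:
    """Render the long read name (4 ``__``-delimited parts)."""
    policy = policy or NamePolicy()
    tuple_.validate()
    block = ",".join(
        encode_segment(s, validate=False)
        for s in sort_segments(tuple_.segments)
    )
    suffix = "".join(f"[{tag}:{value}]" for tag, value in tuple_.extensions)
    hex_id = format(tuple_.tuple_id, f"0{policy.id_hex_width}x")
    return f"{tuple_.prefix}__{hex_id}__{block}__{suffix}"


def _decode_segment_block(block: str) -> list[Segment]:
    if not block:
        raise FormatError("empty segment block")
    segments: list[Segment] = []
    pos = 0
    index = 0
    while True:
        m = _SEGMENT_RE.match(block, pos)
        if not m:
            raise FormatError(
                f"malformed segment at index {index}: {block[pos:pos + 40]!r}"
            )
        seg = Segment(int(m[1]), int(m[2]), m[3], int(m[4]), int(m[5]))
        bad = seg.violations()
        if bad:
            raise FormatError(f"segment {index}: " + "; ".join(bad))
        segments.append(seg)
        pos = m.end()
        index += 1
        if pos == len(block):
            return segments
        if block[pos] != ",":
            raise FormatError(
                f"expected ',' after segment {index - 1}, found {block[pos]!r}"
            )
        pos += 1


def _decode_suffix(suffix: str) -> list[tuple[str, str]]:
    extensions: list[tuple[str, str]] = []
    pos = 0
    while pos < len(suffix):
        m = _EXTENSION_RE.match(suffix, pos)
        if not m:
            raise FormatError(f"malformed suffix near {suffix[pos:pos + 40]!r}")
        extensions.append((m[1], m[2]))
        pos = m.end()
    return extensions


def decode_lrn(name: str) -> ReadTuple:
    """Parse a long read name back into a tuple.

    Read-boundary grouping is not stored in the name (segments of all
    reads are sorted jointly), so the result carries a single read
    holding the flat sorted segment chain.
    """
    parts = name.split("__")
    if len(parts) != 4:
        raise FormatError(
            f"expected 4 double-underscore-delimited parts, found {len(parts)}"
        )
    prefix, hex_id, block, suffix = parts
    if not _PREFIX_RE.match(prefix):
        raise FormatError(f"prefix must match [A-Za-z0-9-]*, got {prefix!r}")
    if not _HEX_RE.match(hex_id):
        raise FormatError(f"non-hexadecimal tuple ID {hex_id!r}")
    tuple_id = int(hex_id, 16)
    if tuple_id < 1:
        raise FormatError(f"tuple_id must be >= 1, got {tuple_id}")
    segments = _decode_segment_block(block)
    extensions = _decode_suffix(suffix)
    return ReadTuple(tuple_id=tuple_id, reads=[Read(segments)],
                     prefix=prefix, extensions=extensions)


def encode_srn(tuple_or_id: ReadTuple | int,
               policy: NamePolicy | None = None) -> str:
    """Render the short read name: ``#`` + zero-padded lowercase hex ID."""
    policy = policy or NamePolicy()
    tid = tuple_or_id.tuple_id if isinstance(tuple_or_id, ReadTuple) else tuple_or_id
    if tid < 1:
        raise ValidationError(f"tuple_id must be >= 1, got {tid}")
    return "#" + format(tid, f"0{policy.id_hex_width}x")


def decode_srn(name: str) -> int:
    m = _SRN_RE.match(name)
    if not m:
        raise FormatError(f"malformed SRN {name!r}")
    tid = int(m[1], 16)
    if tid < 1:
        raise FormatError(f"tuple_id must be >= 1, got {tid}")
    return tid


def choose_name(tuple_: ReadTuple,
                policy: NamePolicy | None = None) -> tuple[str, bool]:
    """Pick the final read name.

    Returns ``(name, used_srn)``: the LRN while it fits within
    ``policy.max_lrn_length`` (length exactly at the limit is kept),
    otherwise the SRN with ``used_srn=True`` signalling that an SRN–LRN
    correspondence record must be written.
    """
    policy = policy or NamePolicy()
    lrn = encode_lrn(tuple_, policy)
    if len(lrn) <= policy.max_lrn_length or not policy.srn_fallback:
        return lrn, False
    return encode_srn(tuple_, policy), True


def validate_name(name: str) -> list[str]:
    """Lint a read name; an empty list means well-formed LRN or SRN."""
    if name.startswith("#"):
        try:
            decode_srn(name)
            return []
        except RnfError as exc:
            return [str(exc)]
    try:
        decode_lrn(name)
        return []
    except RnfError as exc:
        return [str(exc)]


def hex_width_for(max_id: int) -> int:
    """Padding width so the largest ID in a batch prints without overflow."""
    return max(1, len(format(max(max_id, 1), "x")))


def assign_names(
    tuples: Sequence[ReadTuple],
    policy: NamePolicy | None = None,
) -> tuple[list[tuple[str, bool]], list[tuple[str, str]], NamePolicy]:
    """Batch naming with a shared hex width and uniqueness enforcement.

    Returns per-tuple ``(name, used_srn)`` pairs, the correspondence rows
    ``(srn, lrn)`` for tuples that fell back to the SRN, and the policy
    actually used (width derived from the batch's maximum ID when no
    policy is supplied).
    """
    if policy is None:
        max_id = max((t.tuple_id for t in tuples), default=1)
        policy = NamePolicy(id_hex_width=hex_width_for(max_id))
    seen: set[int] = set()
    names: list[tuple[str, bool]] = []
    correspondence: list[tuple[str, str]] = []
    for t in tuples:
        if t.tuple_id in seen:
            raise ValidationError(f"duplicate tuple_id {t.tuple_id} in batch")
        seen.add(t.tuple_id)
        name, used_srn = choose_name(t, policy)
        names.append((name, used_srn))
        if used_srn:
            correspondence.append((name, encode_lrn(t, policy)))
    return names, correspondence, policy
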