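"""Coordinate liftover of origin-encoded read names via UCSC chain files.

The chain format is parsed in its native 0-based half-open convention;
conversion to the 1-based closed convention used inside read names
happens exactly once, at the query boundary.  Both endpoints of a
segment must lift through the same chain to the same target chromosome
and strand — anything else yields an unknown-coordinates segment
(coordinates zeroed, direction ``N``), never an approximate interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import io as rio
from .model import (
    NamePolicy,
    ReadTuple,
    RnfError,
    Segment,
    choose_name,
    decode_lrn,
    encode_lrn,
    hex_width_for,
)

__all__ = [
    "ChainParseError",
    "ChainIndex",
    "LiftStats",
    "load_chain",
    "lift_segment",
    "lift_fastq",
]


class ChainParseError(RnfError):
    pass


@dataclass(frozen=True)
class _Block:
    """One ungapped aligned block of a chain (0-based half-open source)."""

    s_start: int
    s_end: int
    t_chrom: str
    t_size: int
    t_strand: str
    t_start: int  # strand-local, as in the chain file
    score: int
    chain_order: int


@dataclass
class ChainIndex:
    """Position-level source → target lookup built from a chain file."""

    blocks_by_chrom: dict[str, list[_Block]] = field(default_factory=dict)

    def map_position(
        self, chrom: str, pos: int
    ) -> tuple[str, int, str, int] | None:
        """Map a 1-based source position.

        Returns ``(target_chrom, target_pos_1based, target_strand,
        chain_order)`` or ``None`` when no chain covers the position.
        Overlapping chains are resolved by highest score, ties by file
        order.
        """
        p = pos - 1
        best: tuple[int, int, _Block] | None = None
        for block in self.blocks_by_chrom.get(chrom, ()):
            if block.s_start <= p < block.s_end:
                key = (-block.score, block.chain_order, block)
                if best is None or key[:2] < best[:2]:
                    best = key
        if best is None:
            return None
        block = best[2]
        offset = p - block.s_start
        q_local = block.t_start + offset
        if block.t_strand == "+":
            q0 = q_local
        else:
            q0 = block.t_size - 1 - q_local
        return block.t_chrom, q0 + 1, block.t_strand, block.chain_order


def load_chain(path: str) -> ChainIndex:
    """Parse a UCSC chain file into a queryable index.

    Header lines are ``chain score tName tSize tStrand tStart tEnd qName
    qSize qStrand qStart qEnd [id]`` followed by ``size [dt dq]`` block
    lines; the final block has no gap fields.  Block arithmetic is
    checked against the declared interval ends.
    """
    index = ChainIndex()
    chain_order = 0
    with open(path) as handle:
        lines = handle.read().splitlines()

    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        fields = line.split()
        if fields[0] != "chain":
            raise ChainParseError(f"{path}:{i + 1}: expected 'chain' header")
        if len(fields) not in (12, 13):
            raise ChainParseError(
                f"{path}:{i + 1}: chain header has {len(fields)} fields, "
                "expected 12 or 13"
            )
        try:
            score = int(fields[1])
            t_name, t_size = fields[2], int(fields[3])
            t_strand = fields[4]
            t_start, t_end = int(fields[5]), int(fields[6])
            q_name, q_size = fields[7], int(fields[8])
            q_strand = fields[9]
            q_start, q_end = int(fields[10]), int(fields[11])
        except ValueError as exc:
            raise ChainParseError(f"{path}:{i + 1}: {exc}") from exc
        if t_strand != "+":
            raise ChainParseError(
                f"{path}:{i + 1}: source strand must be '+', got {t_strand!r}"
            )
        if q_strand not in "+-":
            raise ChainParseError(
                f"{path}:{i + 1}: target strand must be '+' or '-'"
            )
        header_line = i + 1
        i += 1

        s_pos, q_pos = t_start, q_start
        blocks: list[_Block] = []
        closed = False
        while i < n:
            line = lines[i].strip()
            if not line:
                break
            parts = line.split()
            try:
                nums = [int(x) for x in parts]
            except ValueError as exc:
                raise ChainParseError(f"{path}:{i + 1}: {exc}") from exc
            if len(nums) == 1:
                size = nums[0]
                dt = dq = 0
                closed = True
            elif len(nums) == 3:
                size, dt, dq = nums
            else:
                raise ChainParseError(
                    f"{path}:{i + 1}: expected 1 or 3 integers, got {len(nums)}"
                )
            blocks.append(_Block(
                s_start=s_pos, s_end=s_pos + size,
                t_chrom=q_name, t_size=q_size, t_strand=q_strand,
                t_start=q_pos, score=score, chain_order=chain_order,
            ))
            s_pos += size + dt
            q_pos += size + dq
            i += 1
            if closed:
                break
        if not closed:
            raise ChainParseError(
                f"{path}:{header_line}: chain truncated (no final block line)"
            )
        if s_pos != t_end or q_pos != q_end:
            raise ChainParseError(
                f"{path}:{header_line}: block sizes do not sum to the "
                f"declared intervals (source ends at {s_pos}, expected "
                f"{t_end}; target ends at {q_pos}, expected {q_end})"
            )
        index.blocks_by_chrom.setdefault(t_name, []).extend(blocks)
        chain_order += 1
    return index


_FLIP = {"F": "R", "R": "F", "N": "N"}


def lift_segment(
    segment: Segment,
    index: ChainIndex,
    source_names: dict[int, str],
    target_ids: dict[str, int],
) -> tuple[Segment, str]:
    """Lift one segment; returns ``(segment, status)``.

    Status is ``"unchanged"`` for segments with nothing to lift (unknown
    chromosome or coordinates), ``"lifted"`` on success, ``"unmapped"``
    when either endpoint fails to lift consistently — in which case the
    coordinates are zeroed and the direction set to ``N``.
    """
    if segment.chromosome_id == 0 or segment.left == 0 or segment.right == 0:
        return segment, "unchanged"
    unknown = Segment(segment.genome_id, segment.chromosome_id, "N", 0, 0)
    src = source_names.get(segment.chromosome_id)
    if src is None:
        return unknown, "unmapped"
    a = index.map_position(src, segment.left)
    b = index.map_position(src, segment.right)
    if a is None or b is None:
        return unknown, "unmapped"
    a_chrom, a_pos, a_strand, a_chain = a
    b_chrom, b_pos, b_strand, b_chain = b
    if a_chrom != b_chrom or a_strand != b_strand or a_chain != b_chain:
        return unknown, "unmapped"
    if a_strand == "+":
        left, right = a_pos, b_pos
        direction = segment.direction
    else:
        left, right = b_pos, a_pos
        direction = _FLIP[segment.direction]
    if left > right:
        return unknown, "unmapped"
    tgt_id = target_ids.get(a_chrom)
    if tgt_id is None:
        return unknown, "unmapped"
    return Segment(segment.genome_id, tgt_id, direction, left, right), "lifted"


@dataclass
class LiftStats:
    records: int = 0
    segments_lifted: int = 0
    segments_unmapped: int = 0
    segments_unchanged: int = 0
    records_with_unmapped: int = 0

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as out:
            for key in ("records", "segments_lifted", "segments_unmapped",
                        "segments_unchanged", "records_with_unmapped"):
                out.write(f"{key}\t{getattr(self, key)}\n")


def lift_fastq(
    in_path: str,
    out_path: str,
    index: ChainIndex,
    source_names: dict[int, str],
    target_ids: dict[str, int],
    summary_path: str | None = None,
) -> LiftStats:
    """Re-encode every read name in a FASTQ after lifting its segments."""
    stats = LiftStats()
    entries: list[tuple[ReadTuple, list[tuple[str, str]]]] = []
    max_id = 1
    for idx, (name, seq, qual) in enumerate(rio.read_fastq(in_path), start=1):
        try:
            tuple_ = decode_lrn(name)
        except RnfError as exc:
            raise RnfError(f"{in_path}: record {idx}: {exc}") from exc
        any_unmapped = False
        for read in tuple_.reads:
            lifted = []
            for seg in read.segments:
                new_seg, status = lift_segment(seg, index, source_names,
                                               target_ids)
                lifted.append(new_seg)
                if status == "lifted":
                    stats.segments_lifted += 1
                elif status == "unmapped":
                    stats.segments_unmapped += 1
                    any_unmapped = True
                else:
                    stats.segments_unchanged += 1
            read.segments = lifted
        stats.records += 1
        if any_unmapped:
            stats.records_with_unmapped += 1
        max_id = max(max_id, tuple_.tuple_id)
        entries.append((tuple_, [(seq, qual)]))
    policy = NamePolicy(id_hex_width=hex_width_for(max_id))
    names = []
    corr = []
    for tuple_, _ in entries:
        name, used_srn = choose_name(tuple_, policy)
        names.append(name)
        if used_srn:
            corr.append((name, encode_lrn(tuple_, policy)))
    rio.write_fastq(
        out_path,
        ((name, seqs[0][0], seqs[0][1])
         for name, (_, seqs) in zip(names, entries)),
    )
    if corr:
        rio.write_correspondence(rio.correspondence_path(out_path), corr)
    if summary_path:
        stats.write_tsv(summary_path)
    return stats
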