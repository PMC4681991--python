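"""Minimal built-in read simulator and sample mixer.

The simulator samples reads as genomic substrings with a uniform
substitution error model and records the true origin interval directly
in each read's name, so the whole downstream toolchain can be exercised
without any external simulator.  The mixer merges several origin-named
read sets into one (contamination / metagenome designs), re-assigning
genome IDs and tuple IDs so provenance stays unambiguous.

Deliberately out of scope: indels, quality-dependent error profiles,
coverage/GC bias, genomic mutations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import io as rio
from .model import (
    NamePolicy,
    Read,
    ReadTuple,
    RnfError,
    Segment,
    decode_lrn,
    hex_width_for,
)

__all__ = ["SimulationSpec", "SimulationResult", "simulate", "mix"]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class SimulationSpec:
    n_reads: int
    read_length: int
    substitution_error_rate: float = 0.0
    paired: bool = False
    fragment_mean: float = 500.0
    fragment_sd: float = 50.0
    rng_seed: int = 1
    genome_id: int = 1
    prefix: str = "sim"

    def validate(self) -> None:
        if self.n_reads < 0:
            raise RnfError("n_reads must be >= 0")
        if self.read_length < 1:
            raise RnfError("read_length must be >= 1")
        if not 0.0 <= self.substitution_error_rate <= 1.0:
            raise RnfError("substitution_error_rate must be in [0, 1]")
        if self.paired and (self.fragment_mean <= 0 or self.fragment_sd < 0):
            raise RnfError("fragment_mean must be > 0 and fragment_sd >= 0")
        if self.genome_id < 1:
            raise RnfError("genome_id must be >= 1")


@dataclass(frozen=True)
class SimulationResult:
    fastq_paths: tuple[str, ...]
    correspondence_path: str | None
    n_reads: int


def _add_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    hits = rng.random(len(seq)) < rate
    if not hits.any():
        return seq
    out = list(seq)
    for i in np.flatnonzero(hits):
        base = out[i]
        # substitute with a uniformly chosen *different* base
        if base in _BASE_INDEX:
            choice = int(rng.integers(3))
            out[i] = _BASES[(_BASE_INDEX[base] + 1 + choice) % 4]
        else:
            out[i] = _BASES[int(rng.integers(4))]
    return "".join(out)


def simulate(
    fasta_path: str,
    spec: SimulationSpec,
    out_dir: str,
    basename: str | None = None,
) -> SimulationResult:
    """Simulate reads from a FASTA reference into origin-named FASTQ.

    Chromosomes are chosen with probability proportional to their length
    (among those long enough), start positions uniformly, strands with
    equal probability.  In paired mode the fragment length is drawn from
    a normal distribution, rounded and clamped, and the pair is emitted
    in FR orientation (read 1 forward at the fragment's left end, read 2
    reverse at its right end).  Output is byte-deterministic for a given
    seed and spec.
    """
    spec.validate()
    chroms = rio.read_fasta(fasta_path)
    if not chroms:
        raise RnfError(f"{fasta_path}: empty FASTA")
    min_len = spec.read_length
    usable = [(i + 1, name, seq) for i, (name, seq) in enumerate(chroms)
              if len(seq) >= min_len]
    if not usable:
        raise RnfError(
            f"read_length {spec.read_length} is longer than every chromosome"
        )

    rng = np.random.default_rng(spec.rng_seed)
    lengths = np.array([len(seq) for _, _, seq in usable], dtype=float)
    probs = lengths / lengths.sum()
    rl = spec.read_length
    qual = "I" * rl

    entries: list[tuple[ReadTuple, list[tuple[str, str]]]] = []
    for tid in range(1, spec.n_reads + 1):
        ci = int(rng.choice(len(usable), p=probs))
        chrom_id, _, seq = usable[ci]
        L = len(seq)
        if not spec.paired:
            start = int(rng.integers(1, L - rl + 2))
            reverse = bool(rng.integers(2))
            segment = Segment(spec.genome_id, chrom_id,
                              "R" if reverse else "F", start, start + rl - 1)
            read_seq = seq[start - 1:start + rl - 1]
            if reverse:
                read_seq = rio.revcomp(read_seq)
            read_seq = _add_substitutions(
                read_seq, spec.substitution_error_rate, rng)
            entries.append((
                ReadTuple(tuple_id=tid, reads=[Read([segment])],
                          prefix=spec.prefix),
                [(read_seq, qual)],
            ))
        else:
            frag = int(round(rng.normal(spec.fragment_mean, spec.fragment_sd)))
            frag = max(rl, min(frag, L))
            start = int(rng.integers(1, L - frag + 2))
            end = start + frag - 1
            seg1 = Segment(spec.genome_id, chrom_id, "F", start, start + rl - 1)
            seg2 = Segment(spec.genome_id, chrom_id, "R", end - rl + 1, end)
            seq1 = seq[seg1.left - 1:seg1.right]
            seq2 = rio.revcomp(seq[seg2.left - 1:seg2.right])
            seq1 = _add_substitutions(seq1, spec.substitution_error_rate, rng)
            seq2 = _add_substitutions(seq2, spec.substitution_error_rate, rng)
            entries.append((
                ReadTuple(tuple_id=tid, reads=[Read([seg1]), Read([seg2])],
                          prefix=spec.prefix),
                [(seq1, qual), (seq2, qual)],
            ))

    basename = basename or spec.prefix or "reads"
    rio.ensure_dir(out_dir)
    if spec.paired:
        out_paths = [os.path.join(out_dir, f"{basename}_{k}.fq")
                     for k in (1, 2)]
    else:
        out_paths = [os.path.join(out_dir, f"{basename}.fq")]
    policy = NamePolicy(id_hex_width=hex_width_for(spec.n_reads))
    paths, corr = rio.write_rnf_fastq(entries, out_paths, policy)
    return SimulationResult(tuple(paths), corr, spec.n_reads)


def _load_sample(paths: Sequence[str]):
    files = [list(rio.read_fastq(p)) for p in paths]
    counts = {len(f) for f in files}
    if len(counts) > 1:
        raise RnfError(f"paired files differ in record count: {sorted(counts)}")
    records = []
    for idx in range(len(files[0])):
        name = files[0][idx][0]
        tuple_ = decode_lrn(name)
        seqs = [(f[idx][1], f[idx][2]) for f in files]
        records.append((tuple_, seqs))
    return records


def mix(
    samples: Sequence[tuple[Sequence[str] | str, int]],
    out_dir: str,
    basename: str = "mix",
    shuffle_seed: int | None = None,
) -> SimulationResult:
    """Merge origin-named read sets into one contamination/metagenome sample.

    Each sample is ``(fastq path or list of paired paths, genome_id)``;
    genome IDs must be distinct across samples and are rewritten into
    every segment, so decoding the output recovers which sample each
    read came from.  Tuple IDs are re-assigned sequentially over the
    merged output; ordering is deterministic round-robin across samples
    unless ``shuffle_seed`` asks for a seeded shuffle.
    """
    if not samples:
        raise RnfError("no samples to mix")
    gids = [gid for _, gid in samples]
    if len(set(gids)) != len(gids):
        raise RnfError(f"duplicate genome_id across samples: {sorted(gids)}")

    loaded = []
    layout: int | None = None
    for paths, gid in samples:
        if isinstance(paths, (str, os.PathLike)):
            paths = [paths]
        records = _load_sample(list(paths))
        if records:
            n = len(records[0][1])
            if layout is None:
                layout = n
            elif layout != n:
                raise RnfError("all samples must share the same read layout")
        loaded.append((records, gid))
    layout = layout or 1

    # round-robin interleave, then optional seeded shuffle
    merged: list[tuple[ReadTuple, list[tuple[str, str]]]] = []
    cursors = [0] * len(loaded)
    while True:
        progressed = False
        for si, (records, gid) in enumerate(loaded):
            if cursors[si] < len(records):
                tuple_, seqs = records[cursors[si]]
                cursors[si] += 1
                progressed = True
                reads = [
                    Read([Segment(gid, s.chromosome_id, s.direction,
                                  s.left, s.right)
                          for s in read.segments],
                         chimeric=read.chimeric)
                    for read in tuple_.reads
                ]
                merged.append((
                    ReadTuple(tuple_id=0, reads=reads, prefix=tuple_.prefix,
                              extensions=list(tuple_.extensions)),
                    seqs,
                ))
        if not progressed:
            break
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        order = rng.permutation(len(merged))
        merged = [merged[i] for i in order]
    for new_id, (tuple_, _) in enumerate(merged, start=1):
        tuple_.tuple_id = new_id

    rio.ensure_dir(out_dir)
    if layout == 1:
        out_paths = [os.path.join(out_dir, f"{basename}.fq")]
    else:
        out_paths = [os.path.join(out_dir, f"{basename}_{k}.fq")
                     for k in range(1, layout + 1)]
    policy = NamePolicy(id_hex_width=hex_width_for(len(merged)))
    paths, corr = rio.write_rnf_fastq(merged, out_paths, policy)
    return SimulationResult(tuple(paths), corr, len(merged))
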