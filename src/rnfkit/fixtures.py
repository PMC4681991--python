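"""Deterministic toy world for tests, demos and the acceptance checks.

``make_fixtures`` writes, from a single seed: two random reference
genomes ("host" and "contaminant"), origin-named read sets simulated
from each plus their 50/50 mixture, SAM outputs of three scripted
pseudo-mappers against the host reference, and two chain files (an
identity chain and one with a deleted region).  Everything is derived
from one RNG stream, so the same seed reproduces the directory byte for
byte.

Pseudo-mappers (mapping-quality rule is correlated with correctness, as
a real mapper's would be):

* ``perfect`` — contaminant-aware: host reads placed at their true
  origin with MAPQ 60, contaminant reads left unmapped;
* ``blind`` — contaminant-blind: host reads placed correctly with MAPQ
  60, contaminant reads placed at random host positions with MAPQ drawn
  uniformly from 0..60;
* ``noisy`` — over the pure host read set: a known fraction of reads is
  placed at a random wrong position (MAPQ 0..30), the rest correctly
  (MAPQ 40..60).
"""

from __future__ import annotations

import json
import os

import numpy as np
import pysam

from . import io as rio
from .model import RnfError, decode_lrn
from .simmix import SimulationSpec, mix, simulate

__all__ = ["make_fixtures"]

READ_LENGTH = 100
N_READS_PER_GENOME = 1000
NOISY_CORRUPTION = 0.2
GAP_START = 3000  # 0-based, on host chr1
GAP_LENGTH = 1000


def _random_genome(rng: np.random.Generator, chrom_sizes: dict[str, int]):
    return [(name, "".join(np.array(list("ACGT"))[rng.integers(0, 4, size)]))
            for name, size in chrom_sizes.items()]


def _write_fasta(path: str, chroms, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in chroms:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


def _sam_header(chroms) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in chroms],
    }


def _aligned(header, name, seq, qual, ref_id, pos1, reverse, mapq):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = 16 if reverse else 0
    a.reference_id = ref_id
    a.reference_start = pos1 - 1
    a.mapping_quality = mapq
    a.cigartuples = [(0, len(seq))]
    a.query_sequence = rio.revcomp(seq) if reverse else seq
    a.query_qualities = pysam.qualitystring_to_array(
        qual[::-1] if reverse else qual)
    return a


def _unaligned(header, name, seq, qual):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = 4
    a.reference_id = -1
    a.reference_start = -1
    a.mapping_quality = 0
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array(qual)
    return a


def _truth_segment(name: str):
    tuple_ = decode_lrn(name)
    segments = tuple_.segments
    if len(segments) != 1:
        raise RnfError(f"fixture reads are single-segment, got {name!r}")
    return tuple_, segments[0]


def _random_wrong_position(rng, chrom_lengths, truth_seg, host_ids,
                           tolerance: int = 5):
    """Uniform random placement rejected until it cannot match the truth."""
    names = list(chrom_lengths)
    while True:
        ci = int(rng.integers(len(names)))
        chrom = names[ci]
        pos = int(rng.integers(1, chrom_lengths[chrom] - READ_LENGTH + 2))
        reverse = bool(rng.integers(2))
        if (host_ids.get(chrom) == truth_seg.chromosome_id
                and abs(pos - truth_seg.left) <= tolerance
                and (truth_seg.direction == "R") == reverse):
            continue
        return chrom, pos, reverse


def _write_identity_chain(path: str, chroms) -> None:
    with open(path, "w") as out:
        for name, seq in chroms:
            n = len(seq)
            out.write(f"chain 1000 {name} {n} + 0 {n} {name} {n} + 0 {n} 1\n")
            out.write(f"{n}\n\n")


def _write_gapped_chain(path: str, chroms) -> None:
    """chr1 loses GAP_LENGTH bases starting at GAP_START; others identity."""
    with open(path, "w") as out:
        for name, seq in chroms:
            n = len(seq)
            if name == "chr1":
                tgt = n - GAP_LENGTH
                out.write(
                    f"chain 900 {name} {n} + 0 {n} {name} {tgt} + 0 {tgt} 1\n"
                )
                out.write(f"{GAP_START} {GAP_LENGTH} 0\n")
                out.write(f"{n - GAP_START - GAP_LENGTH}\n\n")
            else:
                out.write(
                    f"chain 900 {name} {n} + 0 {n} {name} {n} + 0 {n} 2\n")
                out.write(f"{n}\n\n")


def make_fixtures(seed: int, out_dir: str) -> dict:
    """Write the toy world; returns (and saves) the manifest."""
    rio.ensure_dir(out_dir)
    rng = np.random.default_rng(seed)

    host = _random_genome(rng, {"chr1": 6000, "chr2": 4000})
    contaminant = _random_genome(rng, {"chrC": 10000})
    host_fa = os.path.join(out_dir, "host.fa")
    cont_fa = os.path.join(out_dir, "contaminant.fa")
    _write_fasta(host_fa, host)
    _write_fasta(cont_fa, contaminant)
    host_ids = {name: i + 1 for i, (name, _) in enumerate(host)}
    host_lengths = {name: len(seq) for name, seq in host}

    seed_host, seed_cont = int(rng.integers(2**31)), int(rng.integers(2**31))
    host_res = simulate(host_fa, SimulationSpec(
        n_reads=N_READS_PER_GENOME, read_length=READ_LENGTH,
        rng_seed=seed_host, genome_id=1, prefix="host"), out_dir, "host_reads")
    cont_res = simulate(cont_fa, SimulationSpec(
        n_reads=N_READS_PER_GENOME, read_length=READ_LENGTH,
        rng_seed=seed_cont, genome_id=2, prefix="cont"), out_dir, "cont_reads")
    mix_res = mix(
        [(host_res.fastq_paths[0], 1), (cont_res.fastq_paths[0], 2)],
        out_dir, basename="mixed_reads")

    mixed = list(rio.read_fastq(mix_res.fastq_paths[0]))
    host_reads = list(rio.read_fastq(host_res.fastq_paths[0]))
    header = pysam.AlignmentHeader.from_dict(_sam_header(host))
    id_to_name = {v: k for k, v in host_ids.items()}

    perfect_sam = os.path.join(out_dir, "perfect.sam")
    blind_sam = os.path.join(out_dir, "blind.sam")
    noisy_sam = os.path.join(out_dir, "noisy.sam")

    with pysam.AlignmentFile(perfect_sam, "w", header=header) as out:
        for name, seq, qual in mixed:
            _, seg = _truth_segment(name)
            if seg.genome_id == 1:
                chrom = id_to_name[seg.chromosome_id]
                out.write(_aligned(header, name, seq, qual,
                                   header.get_tid(chrom), seg.left,
                                   seg.direction == "R", 60))
            else:
                out.write(_unaligned(header, name, seq, qual))

    with pysam.AlignmentFile(blind_sam, "w", header=header) as out:
        for name, seq, qual in mixed:
            _, seg = _truth_segment(name)
            if seg.genome_id == 1:
                chrom = id_to_name[seg.chromosome_id]
                out.write(_aligned(header, name, seq, qual,
                                   header.get_tid(chrom), seg.left,
                                   seg.direction == "R", 60))
            else:
                chrom, pos, reverse = _random_wrong_position(
                    rng, host_lengths, seg, host_ids)
                mapq = int(rng.integers(0, 61))
                out.write(_aligned(header, name, seq, qual,
                                   header.get_tid(chrom), pos, reverse, mapq))

    n_corrupted = 0
    with pysam.AlignmentFile(noisy_sam, "w", header=header) as out:
        for name, seq, qual in host_reads:
            _, seg = _truth_segment(name)
            if rng.random() < NOISY_CORRUPTION:
                n_corrupted += 1
                chrom, pos, reverse = _random_wrong_position(
                    rng, host_lengths, seg, host_ids)
                mapq = int(rng.integers(0, 31))
                out.write(_aligned(header, name, seq, qual,
                                   header.get_tid(chrom), pos, reverse, mapq))
            else:
                chrom = id_to_name[seg.chromosome_id]
                mapq = int(rng.integers(40, 61))
                out.write(_aligned(header, name, seq, qual,
                                   header.get_tid(chrom), seg.left,
                                   seg.direction == "R", mapq))

    identity_chain = os.path.join(out_dir, "identity.chain")
    gapped_chain = os.path.join(out_dir, "gapped.chain")
    _write_identity_chain(identity_chain, host)
    _write_gapped_chain(gapped_chain, host)

    chrom_map = os.path.join(out_dir, "chrom_map.tsv")
    with open(chrom_map, "w") as out:
        for name, cid in host_ids.items():
            out.write(f"{name}\t{cid}\n")

    manifest = {
        "seed": seed,
        "read_length": READ_LENGTH,
        "n_host_reads": N_READS_PER_GENOME,
        "n_contaminant_reads": N_READS_PER_GENOME,
        "noisy_corruption": NOISY_CORRUPTION,
        "gap": {"chrom": "chr1", "start_0based": GAP_START,
                "length": GAP_LENGTH},
        "noisy_corrupted_count": n_corrupted,
        "files": {
            "host_fasta": "host.fa",
            "contaminant_fasta": "contaminant.fa",
            "host_fastq": os.path.basename(host_res.fastq_paths[0]),
            "contaminant_fastq": os.path.basename(cont_res.fastq_paths[0]),
            "mixed_fastq": os.path.basename(mix_res.fastq_paths[0]),
            "perfect_sam": "perfect.sam",
            "blind_sam": "blind.sam",
            "noisy_sam": "noisy.sam",
            "identity_chain": "identity.chain",
            "gapped_chain": "gapped.chain",
            "chrom_map": "chrom_map.tsv",
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
        out.write("\n")
    return manifest
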