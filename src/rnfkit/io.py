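"""FASTA/FASTQ plumbing and the SRN–LRN correspondence file.

Reading goes through Biopython; writing is done directly so that output
is byte-reproducible.  The correspondence file is a headerless
two-column TSV (SRN, LRN) named after the first FASTQ it accompanies
with the suffix ``.sl.tsv``.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .model import NamePolicy, ReadTuple, RnfError, assign_names

__all__ = [
    "read_fasta",
    "read_fastq",
    "write_fastq",
    "correspondence_path",
    "write_correspondence",
    "read_correspondence",
    "write_rnf_fastq",
]

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def read_fasta(path: str) -> list[tuple[str, str]]:
    """Load a FASTA file into memory as (name, uppercase sequence) pairs."""
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(path, "fasta")]


def read_fastq(path: str) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality-string) records."""
    for title, seq, qual in _fastq_iterator(path):
        yield title, seq, qual


def _fastq_iterator(path: str) -> Iterator[tuple[str, str, str]]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            # read names never contain whitespace; keep full title otherwise
            yield title.split()[0] if title else title, seq, qual


def write_fastq(path: str, records: Iterable[tuple[str, str, str]]) -> int:
    n = 0
    with open(path, "w") as out:
        for name, seq, qual in records:
            out.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def correspondence_path(fastq_path: str) -> str:
    return f"{fastq_path}.sl.tsv"


def write_correspondence(path: str, rows: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as out:
        for srn, lrn in rows:
            out.write(f"{srn}\t{lrn}\n")


def read_correspondence(path: str) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise RnfError(
                    f"{path}:{line_no}: expected 2 tab-separated columns, "
                    f"found {len(fields)}"
                )
            mapping[fields[0]] = fields[1]
    return mapping


def write_rnf_fastq(
    entries: Sequence[tuple[ReadTuple, Sequence[tuple[str, str]]]],
    out_paths: Sequence[str],
    policy: NamePolicy | None = None,
    always_correspondence: bool = False,
) -> tuple[list[str], str | None]:
    """Write a batch of tuples as origin-named FASTQ file(s).

    ``entries`` pairs each tuple with one ``(sequence, quality)`` per
    output file; entry *k* of every tuple goes to ``out_paths[k]`` (file
    membership is what records which end a read is — the name itself
    carries only the flat sorted segment block).  Returns the output
    paths and the correspondence-file path (``None`` if no tuple fell
    back to an SRN and ``always_correspondence`` is off).
    """
    for tuple_, seqs in entries:
        if len(seqs) != len(out_paths):
            raise RnfError(
                f"tuple {tuple_.tuple_id}: {len(seqs)} sequences but "
                f"{len(out_paths)} output files"
            )
    names, correspondence, _ = assign_names([t for t, _ in entries], policy)
    for k, path in enumerate(out_paths):
        write_fastq(
            path,
            ((name, entry[1][k][0], entry[1][k][1])
             for (name, _), entry in zip(names, entries)),
        )
    corr_path = None
    if correspondence or always_correspondence:
        corr_path = correspondence_path(out_paths[0])
        write_correspondence(corr_path, correspondence)
    return list(out_paths), corr_path


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
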