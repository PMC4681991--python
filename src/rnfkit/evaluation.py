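"""Truth-aware classification of alignments and MAPQ-parametrized curves.

The unit of evaluation is the individual read (one primary SAM record);
paired ends are scored independently.  Each read's name decodes to its
true origin; the alignment is then classified at every mapping-quality
threshold into one of six exhaustive, mutually exclusive categories, and
the per-threshold counts yield sensitivity, precision and FDR with MAPQ
as the curve parameter.

Definitions (configurable via :class:`EvalConfig`):

* a truth segment *matches* an alignment when genome, chromosome and
  strand agree and the reported leftmost position is within the
  tolerance of the segment's left coordinate;
* a *contaminant* read has no truth segment on the reference genome the
  mapper aligned against;
* a read is *reported* at threshold ``q`` when it is mapped with
  ``MAPQ >= q``;
* precision counts mapped contaminants as false discoveries by default
  (flag-controllable) and is defined as 1 when nothing is reported.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam

from .model import ReadTuple, RnfError, decode_lrn, validate_name

__all__ = [
    "ReadCategory",
    "AlignmentObservation",
    "EvalConfig",
    "CurvePoint",
    "ReadRecord",
    "classify",
    "build_curve",
    "read_alignments",
    "evaluate_alignments",
    "write_curve_tsv",
    "read_curve_tsv",
    "write_audit_tsv",
]


class ReadCategory(enum.Enum):
    CORRECT = "correct"
    WRONG_POSITION = "wrong_position"
    CONTAMINANT_MAPPED = "contaminant_mapped"
    SHOULD_MAP_UNMAPPED = "should_map_unmapped"
    CONTAMINANT_UNMAPPED = "contaminant_unmapped"
    UNDER_THRESHOLD = "under_threshold"


CATEGORY_ORDER = tuple(ReadCategory)


@dataclass(frozen=True)
class AlignmentObservation:
    """One SAM record reduced to what evaluation needs."""

    name: str
    is_mapped: bool
    chrom: str | None = None
    pos: int = 0  # 1-based leftmost
    is_reverse: bool = False
    mapq: int = 0
    is_primary: bool = True
    is_supplementary: bool = False


UNMAPPED = AlignmentObservation(name="", is_mapped=False)


@dataclass(frozen=True)
class EvalConfig:
    ref_genome_id: int = 1
    tolerance: int = 5
    require_strand: bool = True
    chrom_ids: Mapping[str, int] = field(default_factory=dict)
    contaminants_are_false_discoveries: bool = True

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise RnfError("tolerance must be >= 0")


def is_contaminant(truth: ReadTuple, config: EvalConfig) -> bool:
    return not any(s.genome_id == config.ref_genome_id
                   for s in truth.segments)


def _matches_any(obs: AlignmentObservation, truth: ReadTuple,
                 config: EvalConfig) -> bool:
    chrom_id = config.chrom_ids.get(obs.chrom) if obs.chrom else None
    for seg in truth.segments:
        if seg.genome_id != config.ref_genome_id:
            continue
        if chrom_id is None or seg.chromosome_id != chrom_id:
            continue
        if seg.left == 0 or abs(obs.pos - seg.left) > config.tolerance:
            continue
        if config.require_strand:
            if seg.direction == "N":
                continue
            if (seg.direction == "R") != obs.is_reverse:
                continue
        return True
    return False


def classify(obs: AlignmentObservation, truth: ReadTuple,
             config: EvalConfig, q: int) -> ReadCategory:
    """Classify one read's primary alignment at threshold ``q``.

    A chimeric read (multiple true segments) is CORRECT when the primary
    alignment matches any of them.
    """
    contaminant = is_contaminant(truth, config)
    reported = obs.is_mapped and obs.mapq >= q
    if reported:
        if contaminant:
            return ReadCategory.CONTAMINANT_MAPPED
        if _matches_any(obs, truth, config):
            return ReadCategory.CORRECT
        return ReadCategory.WRONG_POSITION
    if contaminant:
        return ReadCategory.CONTAMINANT_UNMAPPED
    if obs.is_mapped:
        return ReadCategory.UNDER_THRESHOLD
    return ReadCategory.SHOULD_MAP_UNMAPPED


@dataclass(frozen=True)
class CurvePoint:
    q: int
    counts: dict[ReadCategory, int]
    sensitivity: float
    precision: float
    fdr: float


@dataclass
class ReadRecord:
    """One evaluated read: its key, decoded truth and primary observation."""

    name: str
    end: int
    truth: ReadTuple
    observation: AlignmentObservation | None = None

    @property
    def obs(self) -> AlignmentObservation:
        return self.observation if self.observation is not None else UNMAPPED


def build_curve(records: Sequence[ReadRecord],
                config: EvalConfig) -> list[CurvePoint]:
    """Sweep the distinct observed MAPQ values (plus sentinel 0).

    Sensitivity = CORRECT / (non-contaminant reads); precision =
    CORRECT / reported (1 when nothing reported); FDR = 1 - precision.
    Points are ordered by increasing threshold.
    """
    thresholds = sorted(
        {r.obs.mapq for r in records if r.obs.is_mapped} | {0}
    )
    n_true = sum(1 for r in records if not is_contaminant(r.truth, config))
    points: list[CurvePoint] = []
    for q in thresholds:
        counts = {cat: 0 for cat in CATEGORY_ORDER}
        for r in records:
            counts[classify(r.obs, r.truth, config, q)] += 1
        correct = counts[ReadCategory.CORRECT]
        discoveries = correct + counts[ReadCategory.WRONG_POSITION]
        if config.contaminants_are_false_discoveries:
            discoveries += counts[ReadCategory.CONTAMINANT_MAPPED]
        sensitivity = correct / n_true if n_true else 0.0
        precision = correct / discoveries if discoveries else 1.0
        points.append(CurvePoint(
            q=q, counts=counts, sensitivity=sensitivity,
            precision=precision, fdr=1.0 - precision,
        ))
    return points


def _resolve_name(qname: str,
                  correspondence: Mapping[str, str] | None) -> str:
    if qname.startswith("#"):
        if correspondence is None:
            raise RnfError(
                f"SRN {qname!r} encountered but no correspondence file supplied"
            )
        try:
            return correspondence[qname]
        except KeyError:
            raise RnfError(
                f"SRN {qname!r} missing from the correspondence file"
            ) from None
    return qname


def read_alignments(
    path: str,
    correspondence: Mapping[str, str] | None = None,
    include_supplementary: bool = False,
) -> tuple[list[ReadRecord], list[str]]:
    """Load a SAM/BAM file into one primary observation per read.

    Reads are keyed by (name, end index); secondary records are ignored
    and supplementary records skipped unless asked for.  QNAMEs must be
    valid origin-encoded names, with SRNs resolved through the
    correspondence mapping.  Returns the records in order of first
    appearance plus a list of warnings (duplicate primaries).
    """
    records: dict[tuple[str, int], ReadRecord] = {}
    warnings: list[str] = []
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_secondary:
                continue
            if rec.is_supplementary and not include_supplementary:
                continue
            name = _resolve_name(rec.query_name, correspondence)
            violations = validate_name(name)
            if violations:
                raise RnfError(
                    f"{path}: QNAME {rec.query_name!r} is not an "
                    f"origin-encoded name: {violations[0]}"
                )
            end = 2 if rec.is_read2 else 1
            key = (name, end)
            obs = AlignmentObservation(
                name=name,
                is_mapped=not rec.is_unmapped,
                chrom=rec.reference_name if not rec.is_unmapped else None,
                pos=(rec.reference_start + 1) if not rec.is_unmapped else 0,
                is_reverse=bool(rec.is_reverse),
                mapq=int(rec.mapping_quality),
                is_primary=not (rec.is_secondary or rec.is_supplementary),
                is_supplementary=bool(rec.is_supplementary),
            )
            if key in records:
                if not rec.is_supplementary:
                    warnings.append(
                        f"duplicate primary record for {name!r} end {end}; "
                        "keeping the first"
                    )
                continue
            records[key] = ReadRecord(name=name, end=end,
                                      truth=decode_lrn(name),
                                      observation=obs)
    return list(records.values()), warnings


def evaluate_alignments(
    path: str,
    config: EvalConfig,
    correspondence: Mapping[str, str] | None = None,
) -> tuple[list[ReadRecord], list[CurvePoint], list[str]]:
    records, warnings = read_alignments(path, correspondence)
    curve = build_curve(records, config)
    return records, curve, warnings


_CURVE_COLUMNS = ("q",) + tuple(c.value for c in CATEGORY_ORDER) + (
    "sensitivity", "precision", "fdr")


def write_curve_tsv(curve: Iterable[CurvePoint], path: str) -> None:
    with open(path, "w") as out:
        out.write("\t".join(_CURVE_COLUMNS) + "\n")
        for p in curve:
            row = [str(p.q)]
            row += [str(p.counts[c]) for c in CATEGORY_ORDER]
            row += [f"{p.sensitivity:.6f}", f"{p.precision:.6f}",
                    f"{p.fdr:.6f}"]
            out.write("\t".join(row) + "\n")


def read_curve_tsv(path: str) -> list[CurvePoint]:
    points: list[CurvePoint] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != _CURVE_COLUMNS:
            raise RnfError(f"{path}: unexpected curve TSV header")
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            counts = {c: int(fields[1 + i])
                      for i, c in enumerate(CATEGORY_ORDER)}
            points.append(CurvePoint(
                q=int(fields[0]), counts=counts,
                sensitivity=float(fields[-3]), precision=float(fields[-2]),
                fdr=float(fields[-1]),
            ))
    return points


def write_audit_tsv(records: Sequence[ReadRecord], config: EvalConfig,
                    path: str) -> None:
    """Per-read audit: category at q=0 and the observed MAPQ."""
    with open(path, "w") as out:
        out.write("name\tend\tcategory\tmapq\n")
        for r in records:
            cat = classify(r.obs, r.truth, config, 0)
            out.write(f"{r.name}\t{r.end}\t{cat.value}\t{r.obs.mapq}\n")
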