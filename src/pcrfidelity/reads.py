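"""Consensus-read container and file I/O (FASTA / SAM / truth tables).

A :class:`ConsensusRead` is one strand-specific single-molecule consensus:
its sequence (stored in reference orientation, as in SAM), the number of
sequencing passes that built it, the mapping quality of its alignment, and
per-base consensus quality values.

SAM is the interchange format: pass counts travel in the integer tag ``np``,
strand in the reverse flag, and the truth alignment in the CIGAR. Files are
written as plain-text SAM via pysam.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import MalformedReadError

MAX_QV = 93
MAX_MAPQ = 254

_CIGAR_OPS = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M"}
_OP_CODES = {"M": 0, "I": 1, "D": 2, "S": 4}


@dataclass
class ConsensusRead:
    """One strand-specific consensus read with its truth/real alignment."""

    read_id: str
    sequence: str  # reference orientation (as stored in SAM)
    strand: str  # '+' or '-'
    n_passes: int
    mapq: int
    qualities: np.ndarray  # per-base QV, 0..93, same length as sequence
    reference_name: str
    ref_start: int = 0  # 0-based
    cigar: list[tuple[str, int]] = field(default_factory=list)
    is_chimeric: bool = False

    def __post_init__(self):
        if self.qualities is None:
            self.qualities = np.full(len(self.sequence), MAX_QV, dtype=np.int16)
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.qualities) != len(self.sequence):
            raise MalformedReadError(
                f"read {self.read_id}: quality length != sequence length")
        if not self.cigar:
            self.cigar = [("M", len(self.sequence))]

    @property
    def query_length(self) -> int:
        return len(self.sequence)

    @property
    def aligned_ref_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    def ref_end(self) -> int:
        return self.ref_start + self.aligned_ref_length


_QUAL_CACHE: dict[tuple[int, int], np.ndarray] = {}


def uniform_quals(length: int, qv: int = MAX_QV) -> np.ndarray:
    """Shared constant quality array (treated as read-only by callers)."""
    key = (length, qv)
    if key not in _QUAL_CACHE:
        arr = np.full(length, qv, dtype=np.int16)
        arr.setflags(write=False)
        _QUAL_CACHE[key] = arr
    return _QUAL_CACHE[key]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# SAM

def write_sam(reads: list[ConsensusRead], references: dict[str, str],
              path) -> None:
    """Write reads to a plain-text SAM file with the given references."""
    names = list(references)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(references[n])} for n in names],
    }
    idx = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = idx[r.reference_name]
            a.reference_start = r.ref_start
            a.mapping_quality = r.mapq
            a.cigartuples = [(_OP_CODES[op], n) for op, n in r.cigar]
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.qualities))
            a.set_tag("np", int(r.n_passes), value_type="i")
            if r.is_chimeric:
                a.set_tag("SA", "chimeric", value_type="Z")
            out.write(a)


def read_sam(path) -> list[ConsensusRead]:
    """Load consensus reads from SAM; unmapped records are skipped."""
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            if not a.has_tag("np"):
                raise MalformedReadError(
                    f"read {a.query_name} lacks the pass-count tag 'np'")
            quals = a.query_qualities
            if quals is None:
                raise MalformedReadError(
                    f"read {a.query_name} lacks per-base quality values")
            reads.append(ConsensusRead(
                read_id=a.query_name,
                sequence=a.query_sequence.upper(),
                strand="-" if a.is_reverse else "+",
                n_passes=int(a.get_tag("np")),
                mapq=a.mapping_quality,
                qualities=np.asarray(quals, dtype=np.int16),
                reference_name=a.reference_name,
                ref_start=a.reference_start,
                cigar=[(_CIGAR_OPS[op], n) for op, n in a.cigartuples],
                is_chimeric=a.has_tag("SA"),
            ))
    return reads


# ---------------------------------------------------------------------------
# Truth tables

def write_truth_tsv(truth_records, path) -> None:
    """Truth events as TSV, positions 1-based."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["read_id", "template", "strand", "kind", "position",
                    "detail"])
        for rec in truth_records:
            for ev in rec.events:
                w.writerow([rec.read_id, rec.template_of_origin, rec.strand,
                            ev.kind, ev.position + 1, ev.detail])


def emit_reads(reads, truth, references: dict[str, str], outdir) -> dict:
    """Write the read bundle: reads FASTA + truth-aligned SAM + truth TSV.

    Returns the paths written. References must include every sequence the
    reads align to (including inversion-product references).
    """
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads_fasta": outdir / "reads.fasta",
        "reads_sam": outdir / "reads.sam",
        "references_fasta": outdir / "references.fasta",
        "truth_tsv": outdir / "truth.tsv",
    }
    write_fasta({r.read_id: r.sequence for r in reads}, paths["reads_fasta"])
    write_fasta(references, paths["references_fasta"])
    write_sam(reads, references, paths["reads_sam"])
    write_truth_tsv(truth, paths["truth_tsv"])
    return paths
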