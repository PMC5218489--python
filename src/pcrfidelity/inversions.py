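"""Detection of template-switching (inversion) reads at inverted repeats.

For each annotated inverted-repeat element four short references are built —
the correct product, the double-switch product (loop reverse-complemented in
place) and the two single-switch fold-back products — each consisting of the
element as it appears in that product plus 30 nt of its flanking context.
A read is assigned the label of the unique reference it matches with more
than 95% coverage and zero mismatches; anything else (no match, or an
ambiguous pair of matches) is unassigned. Exact matching is deliberate: for
small elements the correct and double references differ by only a couple of
bases, so a single tolerated mismatch would conflate the classes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .dna import revcomp
from .exceptions import CoordinateError, UndefinedRateError
from .reads import ConsensusRead
from .templates import InvertedRepeatElement

LABELS = ("correct", "double", "single-top", "single-bottom")
SWITCH_LABELS = ("double", "single-top", "single-bottom")
DEFAULT_FLANK = 30
DEFAULT_MIN_COVERAGE = 0.95


@dataclass(frozen=True)
class InversionReferenceQuad:
    """The four classification references for one element."""

    element: InvertedRepeatElement
    refs: dict[str, str]
    flank: int = DEFAULT_FLANK

    def items(self):
        return self.refs.items()


def build_inversion_references(template: str,
                               element: InvertedRepeatElement,
                               flank: int = DEFAULT_FLANK
                               ) -> InversionReferenceQuad:
    """Construct the correct/double/single-top/single-bottom references.

    Each reference is the element as it appears in the corresponding
    replication product plus up to ``flank`` adjacent nucleotides on each
    available side:

    * correct — left flank + element + right flank (faithful subsequence);
    * double — the same with the loop reverse-complemented in place;
    * single-top — the fold-back junction of the product anchored at the
      5' end: left flank + inverted element + reverse-complemented left flank;
    * single-bottom — anchored at the 3' end: reverse-complemented right
      flank + element + right flank.
    """
    s, e = element.s0, element.e0
    st = element.stem_length
    if s < 0 or e > len(template):
        raise CoordinateError("element lies outside the template")
    el = template[s:e]
    left = template[max(0, s - flank):s]
    right = template[e:e + flank]
    double_el = el[:st] + revcomp(el[st:len(el) - st]) + el[len(el) - st:]
    refs = {
        "correct": left + el + right,
        "double": left + double_el + right,
        "single-top": left + revcomp(el) + revcomp(left),
        "single-bottom": revcomp(right) + el + right,
    }
    return InversionReferenceQuad(element=element, refs=refs, flank=flank)


def _matches(read_seq: str, ref: str, min_coverage: float) -> bool:
    """True if the read contains >min_coverage of ``ref`` with zero edits.

    A full-reference exact occurrence (either read orientation) always
    counts. Truncated coverage is honoured only at read ends — a consensus
    read can be cut short, but an internal mismatch must never be bridged.
    """
    max_trim = int(len(ref) * (1.0 - min_coverage))  # strictly > coverage
    for target in (read_seq, revcomp(read_seq)):
        if ref in target:
            return True
        for trim in range(1, max_trim + 1):
            if len(ref) - trim <= min_coverage * len(ref):
                break
            if target.startswith(ref[trim:]) or target.endswith(ref[:-trim]):
                return True
    return False


def classify_inversion_read(read, quad: InversionReferenceQuad,
                            min_coverage: float = DEFAULT_MIN_COVERAGE
                            ) -> str | None:
    """Label of the unique matching reference, or None (unassigned).

    Accepts a :class:`ConsensusRead` or a plain sequence string.
    """
    seq = read.sequence if isinstance(read, ConsensusRead) else read
    hits = [label for label, ref in quad.items()
            if _matches(seq, ref, min_coverage)]
    return hits[0] if len(hits) == 1 else None


@dataclass
class InversionCallSet:
    """Per-strand class counts for one element."""

    counts: dict[str, dict[str, int]] = field(default_factory=lambda: {
        strand: {**{lab: 0 for lab in LABELS}, "unassigned": 0}
        for strand in "+-"})
    total_scanned: int = 0

    def add(self, strand: str, label: str | None) -> None:
        self.counts[strand][label if label is not None else "unassigned"] += 1
        self.total_scanned += 1

    def class_total(self, label: str) -> int:
        return sum(self.counts[s][label] for s in "+-")

    def switching_total(self) -> int:
        return sum(self.class_total(lab) for lab in SWITCH_LABELS)


def scan_reads(reads, quad: InversionReferenceQuad,
               min_coverage: float = DEFAULT_MIN_COVERAGE,
               min_passes: int = 3) -> InversionCallSet:
    """Classify every read with at least ``min_passes`` passes."""
    calls = InversionCallSet()
    for read in reads:
        if isinstance(read, ConsensusRead):
            if read.n_passes < min_passes:
                continue
            strand = read.strand
        else:
            strand = "+"
        calls.add(strand, classify_inversion_read(read, quad, min_coverage))
    return calls


def inversion_rates(calls: InversionCallSet) -> dict:
    """Percentages of scanned reads per inversion class and combined.

    ``total_pct`` is the headline number: the percentage of scanned strands
    carrying any template-switching signature. Classes never observed are
    reported as "n.d." in text reports; here they are plain zeros.
    """
    if calls.total_scanned == 0:
        raise UndefinedRateError("no reads scanned")
    per_class = {lab: 100.0 * calls.class_total(lab) / calls.total_scanned
                 for lab in LABELS}
    per_strand = {
        strand: {lab: 100.0 * calls.counts[strand][lab] / calls.total_scanned
                 for lab in LABELS}
        for strand in "+-"}
    return {
        "total_pct": 100.0 * calls.switching_total() / calls.total_scanned,
        "per_class_pct": per_class,
        "per_strand_pct": per_strand,
        "unassigned": sum(calls.counts[s]["unassigned"] for s in "+-"),
        "total_scanned": calls.total_scanned,
    }
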