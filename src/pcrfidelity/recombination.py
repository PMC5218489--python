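"""PCR-mediated recombination from co-amplified marker-bearing homologs.

Two homologous templates differing only at single-base markers are
co-amplified; a chimeric (recombinant) strand carries markers from both.
Marker identities are called per read (requiring the two flanking bases on
each side of the marker to match the shared reference), switches are counted
as transitions between consecutive *valid* calls, and the per-base rate is

    raw = 2 * N_re / N_total

where the factor 2 compensates for cryptic events — switches between
identical template copies, invisible to marker-based detection in a 50:50
mix — and ``N_total`` is the total number of analyzed consensus bases.
The raw rate is then normalized per doubling with e = raw * 2 / n.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .exceptions import CoordinateError, UndefinedRateError
from .rates import normalize_per_doubling
from .reads import ConsensusRead
from .templates import MarkerTable

VALID_CALLS = ("A", "B")


@dataclass
class MarkerVector:
    """Per-marker template calls for one read: 'A', 'B' or 'invalid'."""

    read_id: str
    strand: str
    calls: list[str]

    def valid_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.calls) if c in VALID_CALLS]


def _aligned_read_bases(read: ConsensusRead) -> dict[int, str]:
    """Map each aligned reference position to its read base (None gaps absent)."""
    mapping: dict[int, str] = {}
    qpos, rpos = 0, read.ref_start
    for op, n in read.cigar:
        if op == "M":
            for j in range(n):
                mapping[rpos + j] = read.sequence[qpos + j]
            qpos += n
            rpos += n
        elif op == "D":
            rpos += n
        elif op in ("I", "S"):
            qpos += n
    return mapping


def call_markers(read: ConsensusRead, reference: str, table: MarkerTable,
                 flank: int = 2) -> MarkerVector:
    """Call the template identity at every marker position for one read.

    A call is made only when the read base equals one of the two alleles AND
    the ``flank`` bases on each side are aligned and match the (shared)
    reference; a deleted, unaligned or mismatching context yields 'invalid'.
    ``reference`` is the homolog frame the read is aligned to (the homolog-A
    sequence by convention; flanking context is shared between homologs).
    """
    L = len(reference)
    aligned = _aligned_read_bases(read)
    calls = []
    for marker in table:
        p = marker.position - 1
        if p < 0 or p >= L:
            raise CoordinateError(
                f"marker position {marker.position} outside reference")
        call = "invalid"
        center = aligned.get(p)
        if center is not None:
            context_ok = True
            for off in range(1, flank + 1):
                for q in (p - off, p + off):
                    if q < 0 or q >= L or aligned.get(q) != reference[q]:
                        context_ok = False
                        break
                if not context_ok:
                    break
            if context_ok:
                if center == marker.allele_a:
                    call = "A"
                elif center == marker.allele_b:
                    call = "B"
        calls.append(call)
    return MarkerVector(read.read_id, read.strand, calls)


def count_switches(vector: MarkerVector, strict: bool = False) -> int:
    """Number of template switches evidenced by the marker calls.

    Transitions are counted between consecutive *valid* calls; invalid
    markers are skipped (a switch across a skipped marker still counts once).
    Fewer than two valid calls give zero. With ``strict``, a vector
    containing any invalid call contributes nothing (the conservative
    alternative to bridging across invalid markers).
    """
    if strict and any(c not in VALID_CALLS for c in vector.calls):
        return 0
    valid = [c for c in vector.calls if c in VALID_CALLS]
    return sum(1 for a, b in zip(valid, valid[1:]) if a != b)


def switch_intervals(vector: MarkerVector) -> list[tuple[int, int]]:
    """(i, j) 1-based marker-index pairs flanking each detected switch.

    ``j`` is the first valid marker after ``i``; an event is localized to the
    interval between the two flanking valid markers.
    """
    idx = vector.valid_indices()
    out = []
    for a, b in zip(idx, idx[1:]):
        if vector.calls[a] != vector.calls[b]:
            out.append((a + 1, b + 1))
    return out


def per_interval_distribution(vectors: list[MarkerVector],
                              n_markers: int | None = None) -> Counter:
    """Histogram of detected switch events over marker intervals.

    Keys are (i, j) 1-based marker-index pairs; for fully valid vectors these
    are the adjacent intervals (i, i+1).
    """
    hist: Counter = Counter()
    for v in vectors:
        for interval in switch_intervals(v):
            hist[interval] += 1
    if n_markers is not None:
        for i in range(1, n_markers):
            hist.setdefault((i, i + 1), 0)
    return hist


def fraction_with_event(vectors: list[MarkerVector]) -> float:
    """Percentage of strands with at least one detected switch."""
    if not vectors:
        raise UndefinedRateError("no marker vectors")
    with_event = sum(1 for v in vectors if count_switches(v) >= 1)
    return 100.0 * with_event / len(vectors)


@dataclass
class RecombinationResult:
    """Switch totals and rates for one co-amplified template pair."""

    n_re: int  # detected switch events
    n_total: int  # total analyzed consensus bases
    n: float | None = None  # doubling events used for normalization
    per_interval: Counter = field(default_factory=Counter)
    strands_with_event_pct: float | None = None
    n_strands: int = 0

    @property
    def raw_rate(self) -> float:
        """2*N_re/N_total: detected events doubled for cryptic switches."""
        if self.n_total <= 0:
            raise UndefinedRateError("no analyzed bases")
        return 2.0 * self.n_re / self.n_total

    @property
    def normalized_rate(self) -> float | None:
        if self.n is None:
            return None
        return normalize_per_doubling(self.raw_rate, self.n)

    def as_dict(self) -> dict:
        return {
            "n_re": self.n_re,
            "n_total": self.n_total,
            "raw_rate": self.raw_rate if self.n_total else None,
            "n_doublings": self.n,
            "normalized_rate": self.normalized_rate,
            "strands_with_event_pct": self.strands_with_event_pct,
            "n_strands": self.n_strands,
        }


def recombination_rate(events: int, total_bases: int,
                       n: float | None = None) -> RecombinationResult:
    """Assemble a result from pre-counted events and base totals."""
    if total_bases <= 0:
        raise UndefinedRateError("total_bases must be positive")
    return RecombinationResult(n_re=events, n_total=total_bases, n=n)


def analyze_reads(reads: list[ConsensusRead], reference: str,
                  table: MarkerTable, n: float | None = None,
                  strict: bool = False
                  ) -> tuple[RecombinationResult, list[MarkerVector]]:
    """Full marker-based recombination analysis of a read set.

    ``N_total`` is the summed consensus length of the analyzed reads.
    Vectors with fewer than two valid markers contribute bases but cannot
    contribute events (a small censoring toward zero, documented).
    ``strict`` switches to the conservative convention where any invalid
    marker disqualifies the whole vector from event counting.
    """
    vectors = []
    n_re = 0
    n_total = 0
    for read in reads:
        v = call_markers(read, reference, table)
        vectors.append(v)
        n_re += count_switches(v, strict=strict)
        n_total += read.query_length
    result = recombination_rate(n_re, n_total, n)
    result.per_interval = per_interval_distribution(vectors, len(table))
    result.strands_with_event_pct = fraction_with_event(vectors)
    result.n_strands = len(vectors)
    return result, vectors
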