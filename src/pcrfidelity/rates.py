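"""Error-event classification and rate computation.

Raw per-base error fractions are converted to per-doubling polymerase rates
with the linear propagation model: the observed error fraction after PCR is
``f = n * e / 2`` for a per-doubling rate ``e`` over ``n = log2(yield/input)``
doubling events, so ``e = f * 2 / n``.

Substitution rates are composition-averaged: determined separately for A/T
and G/C source bases and then averaged, which removes the dependence on
amplicon base composition:

    e_AT = (subs from A + subs from T) / (N_A + N_T)
    e_GC = (subs from G + subs from C) / (N_G + N_C)
    e_sub = (e_AT + e_GC) / 2

The G/C numerator here uses C→A, C→G and C→T. (The source formula as printed
lists an A→T term in the G/C numerator; that term is treated as a
typographical slip for C→T — see docs/methods.md.)

Directed substitution counts are tallied in the *sequenced-strand*
orientation (events on reverse-strand consensus reads are complemented), so
strand-specific chemistry such as cytosine-deamination damage shows up as a
directed C→T excess. Complementary-pair spectrum tables are unaffected by
this choice.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dna import (BASES, SPECTRUM_PAIRS, SUBSTITUTIONS, complement,
                  pair_label, seq_array)
from .exceptions import CoordinateError, UndefinedRateError
from .filtering import FilterAudit, FilterPolicy, RATES_POLICY, check_event_quality
from .reads import ConsensusRead
from .templates import AmpliconSpec


@dataclass(frozen=True)
class ErrorEvent:
    """One classified error in reference coordinates/orientation."""

    kind: str  # sub | del | ins
    ref_pos: int  # 0-based reference coordinate
    ref_base: str  # '' for insertions
    read_base: str  # '' for deletions
    qv: int
    strand: str
    read_id: str = ""

    def strand_oriented(self) -> tuple[str, str]:
        """(source, target) as seen on the sequenced strand."""
        if self.strand == "-":
            return complement(self.ref_base), complement(self.read_base)
        return self.ref_base, self.read_base


def classify_errors(read: ConsensusRead, reference: str,
                    gap_events: str = "per-base") -> list[ErrorEvent]:
    """Extract substitution/deletion/insertion events from a read alignment.

    Events are reported in reference coordinates; a deletion's QV is the
    minimum QV of the two flanking read bases (a deletion has no read base).
    ``gap_events``: "per-base" (default) counts every deleted reference base
    and inserted read base as one event; "per-run" counts each contiguous
    gap once, positioned at its first base.
    """
    if gap_events not in ("per-base", "per-run"):
        raise ValueError(f"unknown gap_events mode {gap_events!r}")
    if read.ref_start + read.aligned_ref_length > len(reference):
        raise CoordinateError(
            f"read {read.read_id} alignment exceeds reference length")
    events: list[ErrorEvent] = []
    qpos, rpos = 0, read.ref_start
    quals = read.qualities
    rseq = seq_array(reference)
    qseq = seq_array(read.sequence)
    for op, n in read.cigar:
        if op == "M":
            mism = np.flatnonzero(rseq[rpos:rpos + n] != qseq[qpos:qpos + n])
            for off in mism:
                off = int(off)
                events.append(ErrorEvent(
                    "sub", rpos + off, reference[rpos + off],
                    read.sequence[qpos + off], int(quals[qpos + off]),
                    read.strand, read.read_id))
            qpos += n
            rpos += n
        elif op == "D":
            flank = [int(quals[qpos - 1])] if qpos > 0 else []
            if qpos < len(quals):
                flank.append(int(quals[qpos]))
            qv = min(flank) if flank else 0
            span = 1 if gap_events == "per-run" else n
            for j in range(span):
                events.append(ErrorEvent(
                    "del", rpos + j, reference[rpos + j], "", qv,
                    read.strand, read.read_id))
            rpos += n
        elif op == "I":
            span = 1 if gap_events == "per-run" else n
            for j in range(span):
                events.append(ErrorEvent(
                    "ins", rpos, "", read.sequence[qpos + j],
                    int(quals[qpos + j]), read.strand, read.read_id))
            qpos += n
        elif op == "S":
            qpos += n
        else:  # pragma: no cover
            raise ValueError(f"unsupported CIGAR op {op!r}")
    events.sort(key=lambda e: e.ref_pos)
    return events


# ---------------------------------------------------------------------------
# Counts


@dataclass
class ErrorCounts:
    """Analyzed-base totals and directed event counts.

    ``n_bases[b]`` is the number of analyzed consensus bases whose
    sequenced-strand identity is ``b``; ``subs[(x, y)]`` the directed
    substitution counts in the same orientation.
    """

    n_bases: dict[str, int] = field(
        default_factory=lambda: {b: 0 for b in BASES})
    subs: dict[tuple[str, str], int] = field(
        default_factory=lambda: {p: 0 for p in SUBSTITUTIONS})
    n_deletion: int = 0
    n_insertion: int = 0

    @property
    def n_total(self) -> int:
        return sum(self.n_bases.values())

    @property
    def n_substitutions(self) -> int:
        return sum(self.subs.values())

    def subs_from(self, base: str) -> int:
        return sum(c for (src, _), c in self.subs.items() if src == base)

    def add_event(self, event: ErrorEvent) -> None:
        if event.kind == "sub":
            self.subs[event.strand_oriented()] += 1
        elif event.kind == "del":
            self.n_deletion += 1
        elif event.kind == "ins":
            self.n_insertion += 1

    def add_composition(self, composition: dict[str, int],
                        strand: str) -> None:
        for b, c in composition.items():
            key = complement(b) if strand == "-" else b
            self.n_bases[key] += c

    def merged(self, other: "ErrorCounts") -> "ErrorCounts":
        out = ErrorCounts()
        for b in BASES:
            out.n_bases[b] = self.n_bases[b] + other.n_bases[b]
        for p in SUBSTITUTIONS:
            out.subs[p] = self.subs[p] + other.subs[p]
        out.n_deletion = self.n_deletion + other.n_deletion
        out.n_insertion = self.n_insertion + other.n_insertion
        return out


class _RefComposition:
    """O(1) base composition of reference intervals via prefix sums."""

    def __init__(self, reference: str):
        arr = seq_array(reference)
        self._prefix = {b: np.concatenate(
            ([0], np.cumsum(arr == ord(b)))) for b in BASES}

    def interval(self, start: int, end: int) -> dict[str, int]:
        return {b: int(p[end] - p[start]) for b, p in self._prefix.items()}


def count_errors(reads: list[ConsensusRead], references: dict[str, str],
                 policy: FilterPolicy = RATES_POLICY,
                 amplicons: dict[str, AmpliconSpec] | None = None,
                 masked_sites: dict[str, set[int]] | None = None,
                 audit: FilterAudit | None = None,
                 ) -> tuple[ErrorCounts, list[ErrorEvent]]:
    """Classify and tally errors over filtered reads.

    Primer-region exclusion is symmetric: events inside primer intervals are
    masked *and* the masked reference bases are excluded from the analyzed
    denominators. ``masked_sites`` (0-based positions per reference) gets the
    same symmetric treatment — used for engineered marker positions in
    homolog mixes, where an allele difference is not a replication error.
    Event QVs below the maximum are dropped when the policy demands maximum
    event quality. Pass a :class:`FilterAudit` to accumulate the event-level
    mask tallies into it.
    """
    counts = ErrorCounts()
    kept_events: list[ErrorEvent] = []
    comps = {name: _RefComposition(seq) for name, seq in references.items()}
    masked_sites = {name: set(sites)
                    for name, sites in (masked_sites or {}).items()}
    for read in reads:
        ref = references[read.reference_name]
        spec = (amplicons or {}).get(read.reference_name)
        primer0 = spec.primer_regions0() if (
            spec is not None and policy.exclude_primer_regions) else []
        sites = masked_sites.get(read.reference_name, ())
        events = classify_errors(read, ref)
        for ev in events:
            if any(s <= ev.ref_pos < e for s, e in primer0) or \
                    ev.ref_pos in sites:
                if audit is not None:
                    audit.events_masked_primer += 1
                continue
            if not check_event_quality(ev, policy):
                if audit is not None:
                    audit.events_dropped_qv += 1
                continue
            counts.add_event(ev)
            kept_events.append(ev)
        # analyzed denominator: aligned (M) reference bases outside masks
        rpos = read.ref_start
        for op, n in read.cigar:
            if op == "M":
                seg_start, seg_end = rpos, rpos + n
                comp = comps[read.reference_name].interval(seg_start, seg_end)
                for ps, pe in primer0:
                    os_, oe = max(seg_start, ps), min(seg_end, pe)
                    if os_ < oe:
                        masked = comps[read.reference_name].interval(os_, oe)
                        for b in BASES:
                            comp[b] -= masked[b]
                for pos in sites:
                    if seg_start <= pos < seg_end and not any(
                            s <= pos < e for s, e in primer0):
                        comp[ref[pos]] -= 1
                counts.add_composition(comp, read.strand)
                rpos += n
            elif op == "D":
                rpos += n
    return counts, kept_events


# ---------------------------------------------------------------------------
# Rates


def substitution_rate(counts: ErrorCounts, mode: str = "composition-averaged"):
    """Raw substitution rate(s).

    ``composition-averaged`` returns ``(e_AT, e_GC, e_sub)``; ``plain``
    returns total substitutions / total analyzed bases (the convention for
    plasmid background samples).
    """
    if mode == "plain":
        if counts.n_total == 0:
            raise UndefinedRateError("no analyzed bases")
        return counts.n_substitutions / counts.n_total
    if mode != "composition-averaged":
        raise ValueError(f"unknown mode {mode!r}")
    n_at = counts.n_bases["A"] + counts.n_bases["T"]
    n_gc = counts.n_bases["G"] + counts.n_bases["C"]
    if n_at == 0 or n_gc == 0:
        raise UndefinedRateError("zero A/T or G/C denominator")
    e_at = (counts.subs_from("A") + counts.subs_from("T")) / n_at
    e_gc = (counts.subs_from("G") + counts.subs_from("C")) / n_gc
    return e_at, e_gc, (e_at + e_gc) / 2.0


def indel_rates(counts: ErrorCounts) -> tuple[float, float]:
    """(deletion rate, insertion rate) per analyzed base."""
    if counts.n_total == 0:
        raise UndefinedRateError("no analyzed bases")
    return (counts.n_deletion / counts.n_total,
            counts.n_insertion / counts.n_total)


def doublings_from_yield(yield_mass: float, input_mass: float) -> float:
    """Effective doubling events n = log2(yield / input)."""
    if input_mass <= 0:
        raise UndefinedRateError("input mass must be positive")
    if yield_mass < input_mass:
        raise UndefinedRateError("yield below input: no amplification")
    return math.log2(yield_mass / input_mass)


def normalize_per_doubling(f: float, n: float) -> float:
    """Per-doubling rate e = f*2/n (inverse of the propagation model)."""
    if n <= 0:
        raise UndefinedRateError("doubling count must be positive")
    return f * 2.0 / n


def propagate(e: float, n: float) -> float:
    """Expected raw error fraction after n doublings: f = n*e/2."""
    return n * e / 2.0


def per_cycle_rate(f: float, cycles: int) -> float:
    """Raw fraction converted to a per-PCR-cycle rate."""
    if cycles <= 0:
        raise UndefinedRateError("cycle count must be positive")
    return f / cycles


# ---------------------------------------------------------------------------
# Spectrum


@dataclass
class SpectrumTable:
    """Percent share of each complementary substitution pair."""

    pair_percent: dict[str, float]
    n_events: int

    def as_dict(self) -> dict[str, float]:
        return dict(self.pair_percent)


def mutational_spectrum(counts: ErrorCounts) -> SpectrumTable:
    total = counts.n_substitutions
    if total == 0:
        raise UndefinedRateError("no substitutions: spectrum undefined")
    shares = {}
    for pair in SPECTRUM_PAIRS:
        c = sum(counts.subs[p] for p in pair)
        shares[pair_label(pair)] = 100.0 * c / total
    return SpectrumTable(shares, total)


def directed_fraction(counts: ErrorCounts, src: str, dst: str) -> float:
    """Share of one directed change among all substitutions (0..1)."""
    total = counts.n_substitutions
    if total == 0:
        raise UndefinedRateError("no substitutions")
    return counts.subs[(src, dst)] / total


# ---------------------------------------------------------------------------
# Summary


@dataclass
class RateSummary:
    """Raw and normalized rates for one sample."""

    e_sub_at: float | None
    e_sub_gc: float | None
    e_sub: float
    e_del: float
    e_ins: float
    f: float  # raw per-base substitution fraction used for normalization
    n: float | None = None
    yield_mass: float | None = None
    input_mass: float | None = None
    e_normalized: float | None = None
    e_del_normalized: float | None = None
    e_ins_normalized: float | None = None
    per_cycle: float | None = None

    @property
    def accuracy(self) -> float | None:
        """Bases replicated per expected substitution (1 / e_sub)."""
        e = self.e_normalized if self.e_normalized is not None else self.e_sub
        return 1.0 / e if e > 0 else None

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "e_sub_at", "e_sub_gc", "e_sub", "e_del", "e_ins", "f", "n",
            "yield_mass", "input_mass", "e_normalized", "e_del_normalized",
            "e_ins_normalized", "per_cycle")}
        d["accuracy"] = self.accuracy
        return d


def summarize_rates(counts: ErrorCounts, mode: str = "composition-averaged",
                    yield_mass: float | None = None,
                    input_mass: float | None = None,
                    n: float | None = None,
                    cycles: int | None = None) -> RateSummary:
    """Compute the full rate summary for one sample.

    ``n`` may be given directly or derived from ``yield_mass``/``input_mass``.
    Normalized (per-doubling) rates are filled only when a doubling count is
    available; the per-cycle rate only when ``cycles`` is given.
    """
    if mode == "plain":
        e_at = e_gc = None
        e_sub = substitution_rate(counts, "plain")
    else:
        e_at, e_gc, e_sub = substitution_rate(counts, mode)
    e_del, e_ins = indel_rates(counts)
    if n is None and yield_mass is not None and input_mass is not None:
        n = doublings_from_yield(yield_mass, input_mass)
    summary = RateSummary(e_sub_at=e_at, e_sub_gc=e_gc, e_sub=e_sub,
                          e_del=e_del, e_ins=e_ins, f=e_sub, n=n,
                          yield_mass=yield_mass, input_mass=input_mass)
    if n is not None and n > 0:
        summary.e_normalized = normalize_per_doubling(e_sub, n)
        summary.e_del_normalized = normalize_per_doubling(e_del, n)
        summary.e_ins_normalized = normalize_per_doubling(e_ins, n)
    if cycles is not None:
        summary.per_cycle = per_cycle_rate(e_sub, cycles)
    return summary


def round_sig(x: float, digits: int = 2) -> float:
    """Round to significant figures (report convention: 2 s.f. for rates)."""
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + digits - 1)
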