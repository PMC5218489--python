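"""PCR-process simulator with ground truth.

Two modes share one configuration:

* **closed-form** — per read, event counts are Poisson with per-base mean
  ``f = n*e/2`` for each per-doubling rate ``e`` (the linear error-propagation
  model: errors made early in PCR are copied into later cycles, and averaging
  over cycle of origin gives half the naive ``n*e``). Damage uses
  ``n_cycles * d`` (accrual on resting molecules, one hit opportunity per
  thermal cycle).
* **lineage** — an explicit branching process: each cycle every strand
  replicates with probability ``efficiency_per_cycle``; each replication gives
  the nascent strand new substitutions/indels at the per-doubling rates, may
  switch template to a co-amplified homolog (per-base probability
  ``recomb_rate_per_doubling``), and may emit an inversion-class fold-back
  product at an annotated inverted repeat; damage strikes every molecule every
  cycle. Reads are sampled from the final pool, so the ``f = n*e/2``
  propagation behaviour *emerges* rather than being imposed.

Event identities are drawn in molecule-local (sequenced-strand) orientation:
a C→T deamination on a bottom-strand molecule appears as G→A in reference
orientation. Directed-type draws pick the type first (from the 12-weight
spectrum) and then a position uniformly among bases carrying the source base,
which on the equimolar templates used here is equivalent to a uniform
per-base process and makes empirical spectra converge to the configured one.

Every introduced event is recorded in a :class:`TruthRecord` so downstream
estimators can be validated by parameter recovery instead of real data.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .dna import BASES, SUBSTITUTIONS, SUB_INDEX, complement, revcomp, seq_array
from .exceptions import ConfigError
from .reads import MAX_MAPQ, MAX_QV, ConsensusRead, uniform_quals
from .templates import InvertedRepeatElement, TemplateSet

INVERSION_CLASSES = ("single-top", "single-bottom", "double")

# ---------------------------------------------------------------------------
# Directed-substitution spectra


def spectrum_from_directed(weights: dict[tuple[str, str], float] | dict[str, float]
                           ) -> np.ndarray:
    """Normalise a directed-substitution weight mapping to a 12-vector.

    Keys may be ``('C', 'T')`` tuples or ``"C>T"`` strings.
    """
    vec = np.zeros(12)
    for key, w in weights.items():
        if isinstance(key, str):
            a, b = key.split(">")
            key = (a, b)
        vec[SUB_INDEX[key]] = float(w)
    total = vec.sum()
    if total <= 0:
        raise ConfigError([("spectrum", "weights must sum to a positive value")])
    return vec / total


def spectrum_from_pairs(pair_shares: dict[str, float]) -> np.ndarray:
    """Build a directed 12-vector from complementary-pair shares.

    Pair keys look like ``"A>G/T>C"``; each pair's share is split evenly
    between its two directed members (strand-symmetric polymerase errors).
    """
    directed: dict[tuple[str, str], float] = {}
    for key, share in pair_shares.items():
        left, right = key.split("/")
        for part in (left, right):
            a, b = part.split(">")
            directed[(a, b)] = directed.get((a, b), 0.0) + float(share) / 2.0
    return spectrum_from_directed(directed)


#: Taq polymerase substitution spectrum as measured by single-molecule
#: consensus sequencing (complementary-pair shares, percent).
TAQ_PACBIO_PAIR_SHARES = {
    "A>G/T>C": 66.0, "G>A/C>T": 19.0, "A>T/T>A": 9.3,
    "A>C/T>G": 2.0, "G>C/C>G": 1.6, "G>T/C>A": 2.0,
}
TAQ_PACBIO_SPECTRUM = spectrum_from_pairs(TAQ_PACBIO_PAIR_SHARES)

#: Thermocycling damage: cytosine deamination dominates, read as C→T on the
#: damaged strand (97%), with the remainder spread over the other 11 changes.
DEAMINATION_SPECTRUM = spectrum_from_directed(
    {pair: (0.97 if pair == ("C", "T") else 0.03 / 11)
     for pair in SUBSTITUTIONS})

UNIFORM_SPECTRUM = np.full(12, 1 / 12)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimulationConfig:
    """Parameters of the simulated PCR and sequencing run.

    Rates named ``*_per_doubling`` are probabilities per base per effective
    template doubling; ``damage_rate_per_cycle`` is per base per thermal
    cycle. Exactly one of ``efficiency_per_cycle`` (lineage mode) and
    ``target_doublings`` (closed-form mode) must be set.
    """

    seed: int
    sub_rate_per_doubling: float = 0.0
    sub_spectrum: np.ndarray = field(
        default_factory=lambda: TAQ_PACBIO_SPECTRUM.copy())
    del_rate_per_doubling: float = 0.0
    ins_rate_per_doubling: float = 0.0
    damage_rate_per_cycle: float = 0.0
    damage_spectrum: np.ndarray = field(
        default_factory=lambda: DEAMINATION_SPECTRUM.copy())
    n_cycles: int = 16
    efficiency_per_cycle: float | None = None
    target_doublings: float | None = None
    recomb_rate_per_doubling: float = 0.0
    inversion_probs: dict[int, dict[str, float]] = field(default_factory=dict)
    n_reads: int = 1000
    read_pass_model: tuple[int, int] = (15, 40)
    initial_molecules: int = 8

    def __post_init__(self):
        if isinstance(self.sub_spectrum, dict):
            self.sub_spectrum = spectrum_from_directed(self.sub_spectrum)
        if isinstance(self.damage_spectrum, dict):
            self.damage_spectrum = spectrum_from_directed(self.damage_spectrum)
        self.sub_spectrum = np.asarray(self.sub_spectrum, dtype=float)
        self.damage_spectrum = np.asarray(self.damage_spectrum, dtype=float)
        self.validate()

    @property
    def mode(self) -> str:
        return "lineage" if self.efficiency_per_cycle is not None \
            else "closed-form"

    def validate(self) -> None:
        problems = []
        if self.seed is None:
            problems.append(("seed", "a seed is mandatory for reproducibility"))
        for name in ("sub_rate_per_doubling", "del_rate_per_doubling",
                     "ins_rate_per_doubling", "damage_rate_per_cycle",
                     "recomb_rate_per_doubling"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append((name, f"rate {v} outside [0, 1]"))
        for name in ("sub_spectrum", "damage_spectrum"):
            vec = getattr(self, name)
            if vec.shape != (12,):
                problems.append((name, "spectrum must have 12 directed weights"))
            elif abs(float(vec.sum()) - 1.0) > 1e-9:
                problems.append((name, f"spectrum sums to {vec.sum():.12f}, "
                                       "not 1 within 1e-9"))
            elif (vec < 0).any():
                problems.append((name, "spectrum weights must be non-negative"))
        both = (self.efficiency_per_cycle is not None
                and self.target_doublings is not None)
        neither = (self.efficiency_per_cycle is None
                   and self.target_doublings is None)
        if both:
            problems.append(("efficiency_per_cycle/target_doublings",
                             "exactly one must be given, got both"))
        if neither:
            problems.append(("efficiency_per_cycle/target_doublings",
                             "exactly one must be given, got neither"))
        if self.efficiency_per_cycle is not None and not (
                0.0 < self.efficiency_per_cycle <= 1.0):
            problems.append(("efficiency_per_cycle",
                             "must lie in (0, 1]"))
        if self.target_doublings is not None and self.target_doublings < 0:
            problems.append(("target_doublings", "must be >= 0"))
        if self.n_cycles < 1:
            problems.append(("n_cycles", "must be a positive integer"))
        if self.n_reads < 0:
            problems.append(("n_reads", "must be non-negative"))
        lo, hi = self.read_pass_model
        if not (1 <= lo <= hi):
            problems.append(("read_pass_model",
                             "need 1 <= min_passes <= max_passes"))
        if self.initial_molecules < 1:
            problems.append(("initial_molecules", "must be >= 1"))
        for idx, classes in self.inversion_probs.items():
            for cls, p in classes.items():
                if cls not in INVERSION_CLASSES:
                    problems.append((f"inversion_probs[{idx}]",
                                     f"unknown class {cls!r}"))
                elif not (0.0 <= p <= 1.0):
                    problems.append((f"inversion_probs[{idx}][{cls}]",
                                     f"probability {p} outside [0, 1]"))
            if sum(classes.values()) > 1.0 + 1e-12:
                problems.append((f"inversion_probs[{idx}]",
                                 "class probabilities sum to more than 1"))
        if problems:
            raise ConfigError(problems)
        if self.mode == "closed-form":
            worst = max(self.sub_rate_per_doubling, self.del_rate_per_doubling,
                        self.ins_rate_per_doubling,
                        self.recomb_rate_per_doubling)
            if self.target_doublings and worst * self.target_doublings >= 0.1:
                warnings.warn(
                    "n*e >= 0.1: the linear propagation model f = n*e/2 is a "
                    "first-order approximation and becomes biased here",
                    stacklevel=2)


# ---------------------------------------------------------------------------
# Ground truth


@dataclass(frozen=True)
class TruthEvent:
    kind: str  # sub | del | ins | damage | recomb_switch | inversion
    position: int  # 0-based template coordinate (reference orientation)
    detail: str  # e.g. "G>A", deleted base, partner template, class name


@dataclass
class TruthRecord:
    read_id: str
    template_of_origin: str
    strand: str
    events: list[TruthEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Inversion products


def make_inversion_read(template: str, element: InvertedRepeatElement,
                        cls: str) -> str:
    """Replication product of a cruciform-forming element.

    ``correct``
        the faithful product (the template itself).
    ``double``
        the polymerase crosses to the opposite strand at the stem, copies the
        loop there, and crosses back: the loop is reverse-complemented in
        place and the stems are unchanged.
    ``single-top`` / ``single-bottom``
        one crossover without return: the product follows the reference up to
        the element, traverses it on the opposite strand, and keeps copying
        the opposite strand back toward the end it started from, giving a
        truncated fold-back molecule whose length differs from the amplicon.
    """
    s, e = element.s0, element.e0
    st = element.stem_length
    if cls == "correct":
        return template
    if cls == "double":
        return (template[:s + st] + revcomp(template[s + st:e - st])
                + template[e - st:])
    if cls == "single-top":
        return template[:s] + revcomp(template[:e])
    if cls == "single-bottom":
        return revcomp(template[e:]) + template[s:]
    raise ValueError(f"unknown inversion class {cls!r}")


def inversion_reference_name(template_name: str, element_index: int,
                             cls: str) -> str:
    return f"{template_name}|inv{element_index}|{cls}"


def product_references(templates: TemplateSet,
                       config: SimulationConfig | None = None
                       ) -> dict[str, str]:
    """All reference sequences reads may align to, including fold-back and
    loop-inverted products of annotated elements."""
    refs = templates.references()
    carrier = _element_carrier(templates)
    if carrier is not None:
        for idx, element in enumerate(templates.elements):
            for cls in INVERSION_CLASSES:
                refs[inversion_reference_name(carrier.name, idx, cls)] = \
                    make_inversion_read(carrier.sequence, element, cls)
    return refs


def _element_carrier(templates: TemplateSet):
    if not templates.elements:
        return None
    structured = templates.get_by_role("structured")
    return structured[0] if structured else templates.entries[0]


# ---------------------------------------------------------------------------
# Event machinery shared by both modes


class _TemplateIndex:
    """Per-template base-position lookup for source-base-conditional draws."""

    def __init__(self, sequence: str):
        self.sequence = sequence
        arr = seq_array(sequence)
        self.positions = {b: np.flatnonzero(arr == ord(b)) for b in BASES}

    def draw_position(self, base: str, rng, used: set[int],
                      max_tries: int = 50) -> int | None:
        pool = self.positions[base]
        if pool.size == 0:
            return None
        for _ in range(max_tries):
            pos = int(pool[rng.integers(pool.size)])
            if pos not in used:
                used.add(pos)
                return pos
        return None


def _draw_point_events(kind: str, count: int, spectrum: np.ndarray,
                       index: _TemplateIndex, strand: str, rng,
                       used: set[int]) -> list[TruthEvent]:
    """Draw `count` substitution-like events (subs or damage).

    The directed identity is drawn in molecule-local orientation and stored
    in reference orientation; for '-' strand molecules both the source base
    and the target are complemented.
    """
    events = []
    if count <= 0:
        return events
    types = rng.choice(12, size=count, p=spectrum)
    for t in types:
        src, dst = SUBSTITUTIONS[int(t)]
        if strand == "-":
            src, dst = complement(src), complement(dst)
        pos = index.draw_position(src, rng, used)
        if pos is None:
            continue
        events.append(TruthEvent(kind, pos, f"{src}>{dst}"))
    return events


def _assemble(base_seq: str, subs: dict[int, str], dels: set[int],
              ins: list[tuple[int, str]]) -> tuple[str, list[tuple[str, int]]]:
    """Apply point and indel changes; return (read sequence, cigar)."""
    L = len(base_seq)
    if subs:
        chars = list(base_seq)
        for pos, b in subs.items():
            chars[pos] = b
        base_seq = "".join(chars)
    if not dels and not ins:
        return base_seq, [("M", L)]
    ins_sorted = sorted(ins)
    breakpoints = sorted(set(list(dels) + [p for p, _ in ins_sorted]))
    ins_at: dict[int, list[str]] = {}
    for p, b in ins_sorted:
        ins_at.setdefault(p, []).append(b)
    out = []
    cigar: list[tuple[str, int]] = []

    def push(op, n):
        if n <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    prev = 0
    for p in breakpoints:
        push("M", p - prev)
        out.append(base_seq[prev:p])
        prev = p
        if p in ins_at:
            for b in ins_at[p]:
                out.append(b)
                push("I", 1)
        if p in dels:
            push("D", 1)
            prev = p + 1
    push("M", L - prev)
    out.append(base_seq[prev:])
    return "".join(out), cigar


def _mosaic_sequence(segments: list[tuple[int, str]],
                     refs: dict[str, str], length: int) -> str:
    if len(segments) == 1:
        return refs[segments[0][1]]
    parts = []
    for i, (start, name) in enumerate(segments):
        end = segments[i + 1][0] if i + 1 < len(segments) else length
        parts.append(refs[name][start:end])
    return "".join(parts)


# ---------------------------------------------------------------------------
# Closed-form mode


def _recomb_family(templates: TemplateSet) -> list[str]:
    fam = [e.name for e in templates.entries
           if e.role in ("homolog-A", "homolog-B")]
    return fam if len(fam) >= 2 else []


def _flatten_inversions(templates: TemplateSet, config: SimulationConfig):
    """(element, class, probability) triples plus the total probability."""
    triples = []
    for idx, classes in sorted(config.inversion_probs.items()):
        if idx >= len(templates.elements):
            raise ConfigError([(f"inversion_probs[{idx}]",
                                "no such element in the template set")])
        for cls in INVERSION_CLASSES:
            p = classes.get(cls, 0.0)
            if p > 0:
                triples.append((idx, cls, p))
    return triples, sum(p for _, _, p in triples)


def _simulate_closed_form(templates: TemplateSet, config: SimulationConfig
                          ) -> tuple[list[ConsensusRead], list[TruthRecord]]:
    rng = np.random.default_rng(config.seed)
    entries = templates.entries
    n = float(config.target_doublings)
    indexes = {e.name: _TemplateIndex(e.sequence) for e in entries}
    family = _recomb_family(templates)
    carrier = _element_carrier(templates)
    inv_triples, p_inv = _flatten_inversions(templates, config) \
        if carrier is not None else ([], 0.0)

    lengths = np.array([len(e.sequence) for e in entries], dtype=float)
    tidx = rng.integers(len(entries), size=config.n_reads)
    strands = np.where(rng.random(config.n_reads) < 0.5, "+", "-")
    L = lengths[tidx]
    k_sub = rng.poisson(n * config.sub_rate_per_doubling / 2.0 * L)
    k_del = rng.poisson(n * config.del_rate_per_doubling / 2.0 * L)
    k_ins = rng.poisson(n * config.ins_rate_per_doubling / 2.0 * L)
    k_dmg = rng.poisson(config.n_cycles * config.damage_rate_per_cycle * L)
    k_swi = rng.poisson(n * config.recomb_rate_per_doubling / 2.0 * L) \
        if family else np.zeros(config.n_reads, dtype=int)
    inv_u = rng.random(config.n_reads)
    lo, hi = config.read_pass_model
    passes = rng.integers(lo, hi + 1, size=config.n_reads)
    refs = templates.references()

    reads: list[ConsensusRead] = []
    truth: list[TruthRecord] = []
    for i in range(config.n_reads):
        entry = entries[int(tidx[i])]
        strand = str(strands[i])
        read_id = f"r{i:06d}"
        rec = TruthRecord(read_id, entry.name, strand)

        if (carrier is not None and entry.name == carrier.name
                and inv_u[i] < p_inv):
            acc = 0.0
            for idx, cls, p in inv_triples:
                acc += p
                if inv_u[i] < acc:
                    break
            element = templates.elements[idx]
            seq = make_inversion_read(entry.sequence, element, cls)
            rec.events.append(TruthEvent("inversion", element.s0, cls))
            reads.append(ConsensusRead(
                read_id=read_id, sequence=seq, strand=strand,
                n_passes=int(passes[i]), mapq=MAX_MAPQ,
                qualities=uniform_quals(len(seq)),
                reference_name=inversion_reference_name(entry.name, idx, cls),
                cigar=[("M", len(seq))]))
            truth.append(rec)
            continue

        length = len(entry.sequence)
        segments = [(0, entry.name)]
        if family and entry.name in family and k_swi[i] > 0:
            pos_list = sorted(int(p) for p in
                              rng.integers(1, length, size=int(k_swi[i])))
            for pos in pos_list:
                partner = family[int(rng.integers(len(family)))]
                rec.events.append(TruthEvent("recomb_switch", pos, partner))
                if partner != segments[-1][1]:
                    segments.append((pos, partner))
                else:
                    # cryptic switch: same template, invisible downstream
                    pass
        base_seq = _mosaic_sequence(segments, refs, length)
        index = indexes[entry.name] if len(segments) == 1 \
            else _TemplateIndex(base_seq)

        used: set[int] = set()
        point_events = _draw_point_events(
            "sub", int(k_sub[i]), config.sub_spectrum, index, strand, rng, used)
        point_events += _draw_point_events(
            "damage", int(k_dmg[i]), config.damage_spectrum, index, strand,
            rng, used)
        subs = {}
        for ev in point_events:
            rec.events.append(ev)
            subs[ev.position] = ev.detail.split(">")[1]
        dels: set[int] = set()
        if k_del[i] > 0:
            # deletions avoid substituted positions so every planted point
            # event stays observable in the read
            for _ in range(int(k_del[i])):
                for _try in range(50):
                    pos = int(rng.integers(length))
                    if pos not in used:
                        used.add(pos)
                        dels.add(pos)
                        rec.events.append(
                            TruthEvent("del", pos, base_seq[pos]))
                        break
        ins: list[tuple[int, str]] = []
        if k_ins[i] > 0:
            for pos in rng.integers(0, length + 1, size=int(k_ins[i])):
                b = BASES[int(rng.integers(4))]
                ins.append((int(pos), b))
                rec.events.append(TruthEvent("ins", int(pos), b))

        seq, cigar = _assemble(base_seq, subs, dels, ins)
        reads.append(ConsensusRead(
            read_id=read_id, sequence=seq, strand=strand,
            n_passes=int(passes[i]), mapq=MAX_MAPQ,
            qualities=uniform_quals(len(seq)),
            reference_name=entry.name, cigar=cigar))
        truth.append(rec)
    return reads, truth


# ---------------------------------------------------------------------------
# Lineage mode


@dataclass
class _Molecule:
    segments: list[tuple[int, str]]
    strand: str
    events: list[TruthEvent]
    origin: str
    inversion: tuple[int, str] | None = None  # (element index, class)


def _simulate_lineage(templates: TemplateSet, config: SimulationConfig
                      ) -> tuple[list[ConsensusRead], list[TruthRecord]]:
    rng = np.random.default_rng(config.seed)
    entries = templates.entries
    refs = templates.references()
    indexes = {e.name: _TemplateIndex(e.sequence) for e in entries}
    family = _recomb_family(templates)
    carrier = _element_carrier(templates)
    inv_triples, p_inv = _flatten_inversions(templates, config) \
        if carrier is not None else ([], 0.0)

    pool: list[_Molecule] = []
    for e in entries:
        for j in range(config.initial_molecules):
            pool.append(_Molecule([(0, e.name)], "+" if j % 2 == 0 else "-",
                                  [], e.name))
    n_initial = len(pool)

    for _cycle in range(config.n_cycles):
        rep = rng.random(len(pool)) < config.efficiency_per_cycle
        children = []
        for mol_i in np.flatnonzero(rep):
            mol = pool[int(mol_i)]
            child_strand = "-" if mol.strand == "+" else "+"
            if mol.inversion is not None:
                children.append(_Molecule(mol.segments, child_strand,
                                          [], mol.origin, mol.inversion))
                continue
            length = len(refs[mol.origin])
            if (carrier is not None and mol.origin == carrier.name
                    and p_inv > 0 and rng.random() < p_inv):
                u = rng.random() * p_inv
                acc = 0.0
                for idx, cls, p in inv_triples:
                    acc += p
                    if u < acc:
                        break
                ev = TruthEvent("inversion", templates.elements[idx].s0, cls)
                children.append(_Molecule(mol.segments, child_strand,
                                          mol.events + [ev], mol.origin,
                                          (idx, cls)))
                continue
            events = list(mol.events)
            segments = list(mol.segments)
            if family and mol.origin in family:
                k = rng.poisson(config.recomb_rate_per_doubling * length)
                if k:
                    for pos in sorted(int(p) for p in
                                      rng.integers(1, length, size=k)):
                        partner = family[int(rng.integers(len(family)))]
                        events.append(
                            TruthEvent("recomb_switch", pos, partner))
                        if partner != segments[-1][1]:
                            segments.append((pos, partner))
            used = {ev.position for ev in events
                    if ev.kind in ("sub", "damage", "del")}
            index = indexes[mol.origin]
            events += _draw_point_events(
                "sub", int(rng.poisson(
                    config.sub_rate_per_doubling * length)),
                config.sub_spectrum, index, child_strand, rng, used)
            for _ in range(int(rng.poisson(
                    config.del_rate_per_doubling * length))):
                for _try in range(50):
                    pos = int(rng.integers(length))
                    if pos not in used:
                        used.add(pos)
                        events.append(TruthEvent("del", pos,
                                                 refs[mol.origin][pos]))
                        break
            for _ in range(int(rng.poisson(
                    config.ins_rate_per_doubling * length))):
                events.append(TruthEvent("ins",
                                         int(rng.integers(0, length + 1)),
                                         BASES[int(rng.integers(4))]))
            children.append(_Molecule(segments, child_strand, events,
                                      mol.origin))
        pool.extend(children)
        if config.damage_rate_per_cycle > 0:
            counts = rng.poisson(
                config.damage_rate_per_cycle
                * np.array([len(refs[m.origin]) for m in pool]))
            for mol_i in np.flatnonzero(counts):
                mol = pool[int(mol_i)]
                if mol.inversion is not None:
                    continue
                used = {ev.position for ev in mol.events
                        if ev.kind in ("sub", "damage", "del")}
                mol.events += _draw_point_events(
                    "damage", int(counts[mol_i]), config.damage_spectrum,
                    indexes[mol.origin], mol.strand, rng, used)

    n_doublings = math.log2(len(pool) / n_initial)
    lo, hi = config.read_pass_model
    chosen = rng.integers(len(pool), size=config.n_reads)
    reads: list[ConsensusRead] = []
    truth: list[TruthRecord] = []
    for i, mol_i in enumerate(chosen):
        mol = pool[int(mol_i)]
        read_id = f"r{i:06d}"
        rec = TruthRecord(read_id, mol.origin, mol.strand, list(mol.events))
        if mol.inversion is not None:
            idx, cls = mol.inversion
            seq = make_inversion_read(refs[mol.origin],
                                      templates.elements[idx], cls)
            reads.append(ConsensusRead(
                read_id=read_id, sequence=seq, strand=mol.strand,
                n_passes=int(rng.integers(lo, hi + 1)), mapq=MAX_MAPQ,
                qualities=uniform_quals(len(seq)),
                reference_name=inversion_reference_name(mol.origin, idx, cls),
                cigar=[("M", len(seq))]))
            truth.append(rec)
            continue
        length = len(refs[mol.origin])
        base_seq = _mosaic_sequence(mol.segments, refs, length)
        subs = {ev.position: ev.detail.split(">")[1] for ev in mol.events
                if ev.kind in ("sub", "damage")}
        dels = {ev.position for ev in mol.events if ev.kind == "del"}
        ins = [(ev.position, ev.detail) for ev in mol.events
               if ev.kind == "ins"]
        seq, cigar = _assemble(base_seq, subs, dels, ins)
        reads.append(ConsensusRead(
            read_id=read_id, sequence=seq, strand=mol.strand,
            n_passes=int(rng.integers(lo, hi + 1)), mapq=MAX_MAPQ,
            qualities=uniform_quals(len(seq)),
            reference_name=mol.origin, cigar=cigar))
        truth.append(rec)
    # expose the realised doubling count for downstream normalisation
    simulate_amplification.last_doublings = n_doublings
    return reads, truth


def simulate_amplification(templates: TemplateSet, config: SimulationConfig
                           ) -> tuple[list[ConsensusRead], list[TruthRecord]]:
    """Simulate PCR amplification and consensus sequencing.

    Returns ``(reads, truth)``. In lineage mode the realised doubling count
    ``log2(final/initial molecules)`` is stored on
    ``simulate_amplification.last_doublings`` after the call.
    """
    if config.mode == "closed-form":
        simulate_amplification.last_doublings = config.target_doublings
        return _simulate_closed_form(templates, config)
    return _simulate_lineage(templates, config)


simulate_amplification.last_doublings = None
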