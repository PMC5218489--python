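"""Template construction: artificial amplicons, marker-bearing homolog pairs,
and inverted-repeat (cruciform-forming) elements.

The marker-pair generator mirrors the design of artificial fidelity-assay
amplicons: random equimolar base composition, homopolymer runs capped at 5,
and a second homolog differing only at single-base marker positions spaced at
near-regular intervals so PCR-mediated recombination crossovers can be
localised.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .dna import BASES, max_homopolymer, random_sequence, revcomp
from .exceptions import ConstraintError, CoordinateError

ROLES = ("amplicon", "homolog-A", "homolog-B", "structured", "plasmid")


@dataclass(frozen=True)
class InvertedRepeatElement:
    """An inverted repeat with stem/loop geometry.

    Coordinates are 1-based inclusive (report convention). The first
    ``stem_length`` bases of the element are the reverse complement of its
    last ``stem_length`` bases, so the element can extrude as a cruciform.
    """

    start: int
    end: int
    stem_length: int
    loop_length: int

    def __post_init__(self):
        if self.end - self.start + 1 != 2 * self.stem_length + self.loop_length:
            raise CoordinateError(
                f"element span {self.start}..{self.end} does not equal "
                f"2*stem({self.stem_length}) + loop({self.loop_length})")

    # 0-based half-open accessors used internally
    @property
    def s0(self) -> int:
        return self.start - 1

    @property
    def e0(self) -> int:
        return self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def extract(self, template: str) -> str:
        if self.s0 < 0 or self.e0 > len(template):
            raise CoordinateError(
                f"element {self.start}..{self.end} outside template of length "
                f"{len(template)}")
        return template[self.s0:self.e0]

    def is_consistent_with(self, template: str) -> bool:
        """True if the stems of the element are reverse complements."""
        el = self.extract(template)
        return el[:self.stem_length] == revcomp(el[-self.stem_length:])


@dataclass(frozen=True)
class Marker:
    position: int  # 1-based reference coordinate
    allele_a: str
    allele_b: str


@dataclass
class MarkerTable:
    """Ordered single-base differences distinguishing two homologs."""

    markers: list[Marker]

    def __post_init__(self):
        pos = [m.position for m in self.markers]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise ConstraintError("marker positions must be strictly increasing")
        for m in self.markers:
            if m.allele_a == m.allele_b:
                raise ConstraintError(
                    f"marker at {m.position} has identical alleles")

    def __len__(self):
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def positions0(self) -> list[int]:
        return [m.position - 1 for m in self.markers]

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["position", "allele_A", "allele_B"])
            for m in self.markers:
                w.writerow([m.position, m.allele_a, m.allele_b])

    @classmethod
    def from_tsv(cls, path) -> "MarkerTable":
        markers = []
        with open(path) as fh:
            r = csv.DictReader(fh, delimiter="\t")
            for row in r:
                markers.append(Marker(int(row["position"]),
                                      row["allele_A"], row["allele_B"]))
        return cls(markers)


@dataclass(frozen=True)
class AmpliconSpec:
    """Expected amplicon geometry used for filtering and primer masking."""

    name: str
    expected_length: int
    primer_regions: tuple[tuple[int, int], ...] = ()  # 1-based inclusive

    def primer_regions0(self) -> list[tuple[int, int]]:
        """Primer intervals as 0-based half-open."""
        return [(s - 1, e) for s, e in self.primer_regions]

    def in_primer(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.primer_regions0())


@dataclass
class TemplateEntry:
    name: str
    sequence: str
    role: str = "amplicon"

    def __post_init__(self):
        if self.role not in ROLES:
            raise ConstraintError(f"unknown template role {self.role!r}")
        if set(self.sequence) - set(BASES):
            raise ConstraintError(
                f"template {self.name} contains non-ACGT characters")


@dataclass
class TemplateSet:
    """Reference sequences plus optional marker table and structured elements."""

    entries: list[TemplateEntry]
    marker_table: MarkerTable | None = None
    elements: list[InvertedRepeatElement] = field(default_factory=list)
    primer_regions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ConstraintError("duplicate template names")
        a = self.get_by_role("homolog-A")
        b = self.get_by_role("homolog-B")
        if a and b:
            if len(a[0].sequence) != len(b[0].sequence):
                raise ConstraintError("homolog pair must have equal length")
            if self.marker_table is not None:
                diffs = [i for i, (x, y) in
                         enumerate(zip(a[0].sequence, b[0].sequence)) if x != y]
                if diffs != self.marker_table.positions0():
                    raise ConstraintError(
                        "homologs must differ exactly at marker positions")

    def get(self, name: str) -> TemplateEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def get_by_role(self, role: str) -> list[TemplateEntry]:
        return [e for e in self.entries if e.role == role]

    def references(self) -> dict[str, str]:
        return {e.name: e.sequence for e in self.entries}

    def homolog_pair(self) -> tuple[TemplateEntry, TemplateEntry] | None:
        a = self.get_by_role("homolog-A")
        b = self.get_by_role("homolog-B")
        if a and b:
            return a[0], b[0]
        return None


def _marker_positions(length: int, marker_count: int, margin: int = 4
                      ) -> list[int]:
    """Near-regular marker layout (0-based), anchored close to both ends.

    End-anchoring keeps the recombination-detectable span close to the full
    molecule, so marker-based switch detection is limited by the assay rather
    than by layout censoring.
    """
    span = length - 1 - 2 * margin
    step = span / (marker_count - 1)
    return [margin + round(i * step) for i in range(marker_count)]


def make_artificial_template(length: int, marker_count: int, seed=None
                             ) -> tuple[str, str, MarkerTable]:
    """Generate a homolog pair differing only at marker positions.

    Returns (homolog_A, homolog_B, marker table). The pair has near-equimolar
    base composition, no homopolymer run longer than 5 bases, and markers at
    near-regular intervals.
    """
    if marker_count < 2:
        raise ConstraintError("marker_count must be at least 2")
    if length < marker_count * 10:
        raise ConstraintError(
            f"length {length} too small for {marker_count} markers "
            "(need length >= 10 per marker)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    seq_a = random_sequence(length, rng)
    positions = _marker_positions(length, marker_count)
    chars = list(seq_a)
    markers = []
    for p in positions:
        original = chars[p]
        choices = [b for b in BASES if b != original]
        rng.shuffle(choices)
        for alt in choices:
            chars[p] = alt
            window = "".join(chars[max(0, p - 6):p + 7])
            if max_homopolymer(window) <= 5:
                break
        else:  # pragma: no cover - extremely unlikely after run capping
            chars[p] = choices[0]
        markers.append(Marker(p + 1, original, chars[p]))
    seq_b = "".join(chars)
    return seq_a, seq_b, MarkerTable(markers)


def insert_inverted_repeat(sequence: str, start: int, stem_length: int,
                           loop_length: int, seed=None
                           ) -> tuple[str, InvertedRepeatElement]:
    """Overwrite a slice of ``sequence`` with a synthetic inverted repeat.

    ``start`` is 1-based; the element occupies ``start .. start + 2*stem +
    loop - 1``. The loop is re-drawn until it is not its own reverse
    complement, so the four inversion-classification references stay distinct.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    el_len = 2 * stem_length + loop_length
    s0 = start - 1
    if s0 < 0 or s0 + el_len > len(sequence):
        raise CoordinateError("inverted repeat does not fit in the template")
    stem = random_sequence(stem_length, rng) if stem_length >= 8 else \
        "".join(BASES[i] for i in rng.integers(0, 4, stem_length))
    while True:
        loop = random_sequence(loop_length, rng) if loop_length >= 8 else \
            "".join(BASES[i] for i in rng.integers(0, 4, loop_length))
        if loop != revcomp(loop):
            break
    element_seq = stem + loop + revcomp(stem)
    out = sequence[:s0] + element_seq + sequence[s0 + el_len:]
    element = InvertedRepeatElement(start=start, end=start + el_len - 1,
                                    stem_length=stem_length,
                                    loop_length=loop_length)
    assert element.is_consistent_with(out)
    return out, element
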