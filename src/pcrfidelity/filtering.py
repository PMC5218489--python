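"""Consensus-read and per-event quality filters applied before rate estimation.

The read-level criteria mirror single-molecule fidelity practice: a minimum
number of consensus passes, maximum mapping quality (unambiguous alignment),
a minimum read length relative to the expected amplicon, and removal of
chimeric reads. Event-level criteria (maximum consensus QV at the event,
primer-region masking) are applied during error counting, not here, but the
policy object carries them so one policy describes the whole analysis.

Two presets ship:

* :data:`RATES_POLICY` — error-rate estimation (15-pass minimum, strict).
* :data:`SWITCHING_POLICY` — inversion/recombination scans (3-pass minimum,
  no length cut: fold-back template-switch products are shorter or longer
  than the amplicon by construction).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

from .exceptions import MalformedReadError
from .reads import MAX_MAPQ, MAX_QV, ConsensusRead
from .templates import AmpliconSpec

#: Audit attribution order: each removed read is charged to the first
#: criterion it fails. Survivorship itself is order-independent (conjunction).
CRITERIA = ("passes", "mapq", "length", "chimeric")


@dataclass(frozen=True)
class FilterPolicy:
    min_passes: int = 15
    require_max_event_qv: bool = True
    require_mapq: int = MAX_MAPQ
    min_length_fraction: float = 0.80
    exclude_primer_regions: bool = True
    drop_chimeric: bool = True

    def __post_init__(self):
        if not (0.0 <= self.min_length_fraction <= 1.0):
            raise ValueError("min_length_fraction must lie in [0, 1]")
        if self.min_passes < 0 or self.require_mapq < 0:
            raise ValueError("thresholds must be non-negative")


RATES_POLICY = FilterPolicy()
SWITCHING_POLICY = FilterPolicy(min_passes=3, require_max_event_qv=False,
                                require_mapq=0, min_length_fraction=0.0,
                                drop_chimeric=False)


@dataclass
class FilterAudit:
    """Read counts per removal criterion plus event-level mask tallies."""

    n_input: int = 0
    n_surviving: int = 0
    removed: dict[str, int] = None
    events_masked_primer: int = 0
    events_dropped_qv: int = 0

    def __post_init__(self):
        if self.removed is None:
            self.removed = {c: 0 for c in CRITERIA}

    def check_conservation(self) -> bool:
        return self.n_input == self.n_surviving + sum(self.removed.values())

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_surviving": self.n_surviving,
            "removed": dict(self.removed),
            "events_masked_primer": self.events_masked_primer,
            "events_dropped_qv": self.events_dropped_qv,
        }


def _failing_criterion(read: ConsensusRead, policy: FilterPolicy,
                       expected_length: int | None) -> str | None:
    if read.n_passes is None:
        raise MalformedReadError(f"read {read.read_id} lacks a pass count")
    if read.mapq is None:
        raise MalformedReadError(f"read {read.read_id} lacks a MAPQ value")
    if read.n_passes < policy.min_passes:
        return "passes"
    if read.mapq < policy.require_mapq:
        return "mapq"
    if (expected_length is not None and policy.min_length_fraction > 0
            and read.query_length <
            policy.min_length_fraction * expected_length):
        return "length"
    if policy.drop_chimeric and read.is_chimeric:
        return "chimeric"
    return None


def filter_reads(reads: list[ConsensusRead], policy: FilterPolicy,
                 amplicon: AmpliconSpec | None = None
                 ) -> tuple[list[ConsensusRead], FilterAudit]:
    """Apply read-level criteria; return surviving reads and an audit.

    The length criterion uses the consensus-read length (not aligned length)
    against ``amplicon.expected_length`` and is skipped when no amplicon spec
    is supplied.
    """
    expected = amplicon.expected_length if amplicon is not None else None
    audit = FilterAudit(n_input=len(reads))
    surviving = []
    for read in reads:
        failed = _failing_criterion(read, policy, expected)
        if failed is None:
            surviving.append(read)
        else:
            audit.removed[failed] += 1
    audit.n_surviving = len(surviving)
    return surviving, audit


def check_event_quality(event, policy: FilterPolicy) -> bool:
    """Keep an error event only if its consensus QV is the maximum (93).

    Always keeps the event when the policy's QV requirement is off.
    """
    if not policy.require_max_event_qv:
        return True
    return event.qv == MAX_QV
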