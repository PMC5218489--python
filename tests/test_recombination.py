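import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pcrfidelity as pf
from pcrfidelity.exceptions import CoordinateError

from conftest import make_read


def _vector(calls):
    return pf.MarkerVector("r0", "+", list(calls))


def _perfect_read(sequence, name, read_id="r0"):
    return make_read(sequence=sequence, read_id=read_id,
                     reference_name=name, n_passes=10)


# ---------------------------------------------------------------------------
# marker calling


def test_pure_homolog_reads_call_uniformly(homolog_set):
    a, b = homolog_set.homolog_pair()
    table = homolog_set.marker_table
    va = pf.call_markers(_perfect_read(a.sequence, a.name), a.sequence, table)
    assert va.calls == ["A"] * len(table)
    vb = pf.call_markers(_perfect_read(b.sequence, b.name), a.sequence, table)
    assert vb.calls == ["B"] * len(table)


def test_flanking_mismatch_invalidates_marker(homolog_set):
    a, _ = homolog_set.homolog_pair()
    table = homolog_set.marker_table
    p = table.markers[2].position - 1  # 0-based marker 3
    seq = list(a.sequence)
    flank = p + 2
    seq[flank] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[flank]]
    v = pf.call_markers(_perfect_read("".join(seq), a.name), a.sequence, table)
    expected = ["A"] * len(table)
    expected[2] = "invalid"
    assert v.calls == expected


def test_deletion_spanning_marker_invalidates(homolog_set):
    a, _ = homolog_set.homolog_pair()
    table = homolog_set.marker_table
    p = table.markers[4].position - 1
    seq = a.sequence[:p] + a.sequence[p + 1:]
    read = make_read(sequence=seq, reference_name=a.name,
                     cigar=[("M", p), ("D", 1), ("M", len(a.sequence) - p - 1)])
    v = pf.call_markers(read, a.sequence, table)
    assert v.calls[4] == "invalid"
    assert all(c == "A" for i, c in enumerate(v.calls) if i != 4)


def test_marker_outside_reference_rejected():
    table = pf.MarkerTable([pf.Marker(50, "A", "C")])
    with pytest.raises(CoordinateError):
        pf.call_markers(make_read(sequence="ACGT"), "ACGT", table)


# ---------------------------------------------------------------------------
# switch counting


@pytest.mark.parametrize("calls,expected", [
    ("AAAAA", 0),
    ("AAABB", 1),
    ("ABA", 2),
    (["A", "invalid", "B"], 1),
    (["invalid"] * 5, 0),
    ("A", 0),
])
def test_count_switches_cases(calls, expected):
    assert pf.count_switches(_vector(calls)) == expected


def test_strict_mode_disqualifies_partial_vectors():
    v = _vector(["A", "invalid", "B"])
    assert pf.count_switches(v) == 1
    assert pf.count_switches(v, strict=True) == 0
    clean = _vector("AABB")
    assert pf.count_switches(clean, strict=True) == 1


@given(st.lists(st.sampled_from(["A", "B", "invalid"]), max_size=20))
def test_count_switches_equals_bruteforce(calls):
    """Oracle equivalence: transition count over all consecutive valid-call
    pairs, scanned pairwise by brute force."""
    v = _vector(calls)
    valid_idx = [i for i, c in enumerate(calls) if c in ("A", "B")]
    brute = sum(1 for i, j in zip(valid_idx, valid_idx[1:])
                if calls[i] != calls[j])
    assert pf.count_switches(v) == brute


def test_switch_interval_attribution():
    v = _vector("AAABB")
    assert pf.switch_intervals(v) == [(3, 4)]
    hist = pf.per_interval_distribution([v], n_markers=5)
    assert hist[(3, 4)] == 1
    assert sum(hist.values()) == 1
    # across an invalid marker the interval spans the two flanking valid calls
    assert pf.switch_intervals(_vector(["A", "invalid", "B"])) == [(1, 3)]


# ---------------------------------------------------------------------------
# rates


def test_recombination_rate_closed_form():
    res = pf.recombination_rate(100, 10**6, n=10)
    assert res.raw_rate == pytest.approx(2e-4)
    assert res.normalized_rate == pytest.approx(4e-5)
    assert pf.recombination_rate(0, 10**6).raw_rate == 0.0


def test_published_count_arithmetic():
    """Doubling 19,943 events over 77,725,936 bases gives a 5.13e-4 raw
    per-base rate before per-doubling normalization."""
    res = pf.recombination_rate(19_943, 77_725_936)
    assert pf.round_sig(res.raw_rate, 3) == pytest.approx(5.13e-4)


def test_fraction_with_event_arithmetic():
    vectors = [_vector("AB")] * 23 + [_vector("AA")] * 77
    assert pf.fraction_with_event(vectors) == pytest.approx(23.0)


# ---------------------------------------------------------------------------
# simulation-backed properties


@pytest.fixture(scope="module")
def recomb_run(homolog_set):
    cfg = pf.SimulationConfig(seed=41, recomb_rate_per_doubling=9.6e-5,
                              target_doublings=10.7, n_reads=20_000)
    reads, truth = pf.simulate_amplification(homolog_set, cfg)
    a = homolog_set.homolog_pair()[0]
    result, vectors = pf.analyze_reads(reads, a.sequence,
                                       homolog_set.marker_table, n=10.7)
    return reads, truth, result, vectors


def test_detection_matches_marker_oracle(recomb_run, homolog_set):
    """Marker-based switch detection equals an independent oracle that
    replays the truth switch chain over the marker positions."""
    reads, truth, result, vectors = recomb_run
    table = homolog_set.marker_table
    pair = homolog_set.homolog_pair()
    name_to_call = {pair[0].name: "A", pair[1].name: "B"}
    oracle_total = 0
    for rec in truth:
        switches = sorted((e.position, e.detail) for e in rec.events
                          if e.kind == "recomb_switch")
        calls = []
        for m in table:
            current = rec.template_of_origin
            for pos, partner in switches:
                if pos <= m.position - 1:
                    current = partner
            calls.append(name_to_call[current])
        oracle_total += pf.count_switches(pf.MarkerVector("x", "+", calls))
    assert result.n_re == oracle_total


def test_cryptic_halving_in_5050_mix(recomb_run):
    """Half of all template switches land on the identical co-amplified
    template and are invisible; detected events are ~half of truth (within
    3 s.e. plus the small documented parity/end-censoring bias)."""
    reads, truth, result, _ = recomb_run
    truth_total = sum(1 for rec in truth for e in rec.events
                      if e.kind == "recomb_switch")
    ratio = result.n_re / truth_total
    se = math.sqrt(0.25 / truth_total)
    assert abs(ratio - 0.5) < 3 * se + 0.03


def test_identical_templates_detect_nothing(homolog_set):
    """Switching between indistinguishable templates is cryptic: truth events
    continue at the configured rate but marker detection sees zero."""
    a = homolog_set.homolog_pair()[0]
    twins = pf.TemplateSet(
        entries=[pf.TemplateEntry("T1", a.sequence, "homolog-A"),
                 pf.TemplateEntry("T2", a.sequence, "homolog-B")])
    cfg = pf.SimulationConfig(seed=43, recomb_rate_per_doubling=5e-4,
                              target_doublings=10, n_reads=2000)
    reads, truth = pf.simulate_amplification(twins, cfg)
    assert sum(1 for rec in truth for e in rec.events
               if e.kind == "recomb_switch") > 0
    result, _ = pf.analyze_reads(reads, a.sequence, homolog_set.marker_table,
                                 n=10)
    assert result.n_re == 0


def test_normalized_rate_recovers_configuration(recomb_run):
    """End-to-end: the doubled, per-doubling-normalized rate recovers the
    configured per-base switch rate within 10%."""
    _, _, result, _ = recomb_run
    assert result.normalized_rate == pytest.approx(9.6e-5, rel=0.10)


def test_interval_distribution_uniform(recomb_run, homolog_set):
    """Uniform switch positions give near-uniform interval counts
    (chi-square over the equal-length adjacent intervals)."""
    from scipy import stats
    _, _, result, _ = recomb_run
    k = len(homolog_set.marker_table)
    adjacent = [result.per_interval.get((i, i + 1), 0) for i in range(1, k)]
    assert sum(adjacent) > 1000
    _, p = stats.chisquare(adjacent)
    assert p > 0.01


def test_fraction_with_event_poisson_check(recomb_run):
    """With independent per-read switch draws the strand fraction with >=1
    detected event matches 1 - exp(-m) for per-strand mean m."""
    _, _, result, vectors = recomb_run
    m = result.n_re / len(vectors)
    expected = 100 * (1 - math.exp(-m))
    se = 100 * math.sqrt(expected / 100 * (1 - expected / 100) / len(vectors))
    assert abs(result.strands_with_event_pct - expected) < 3 * se + 0.2
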