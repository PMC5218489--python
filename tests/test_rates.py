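import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pcrfidelity as pf
from pcrfidelity.dna import SUBSTITUTIONS
from pcrfidelity.exceptions import UndefinedRateError

from conftest import make_read


def _counts(n_a=0, n_t=0, n_g=0, n_c=0, subs=None, n_del=0, n_ins=0):
    c = pf.ErrorCounts()
    c.n_bases.update({"A": n_a, "T": n_t, "G": n_g, "C": n_c})
    for key, v in (subs or {}).items():
        a, b = key.split(">")
        c.subs[(a, b)] = v
    c.n_deletion = n_del
    c.n_insertion = n_ins
    return c


# ---------------------------------------------------------------------------
# classification


def test_identical_read_yields_no_events():
    read = make_read(sequence="ACGTACGT")
    assert pf.classify_errors(read, "ACGTACGT") == []


def test_single_substitution_classified():
    read = make_read(sequence="ACAT")
    events = pf.classify_errors(read, "ACGT")
    assert len(events) == 1
    ev = events[0]
    assert (ev.kind, ev.ref_pos, ev.ref_base, ev.read_base) == \
        ("sub", 2, "G", "A")


def test_indel_classification_with_flanking_qv():
    # ref ACGTAC, read with G deleted and an extra T inserted before pos 5
    read = make_read(sequence="ACTATC",
                     qualities=np.array([93, 90, 85, 93, 80, 93]),
                     cigar=[("M", 2), ("D", 1), ("M", 2), ("I", 1), ("M", 1)])
    events = pf.classify_errors(read, "ACGTAC")
    kinds = [(e.kind, e.ref_pos) for e in events]
    assert ("del", 2) in kinds and ("ins", 5) in kinds
    del_ev = next(e for e in events if e.kind == "del")
    assert del_ev.qv == min(90, 85)  # minimum of the flanking read bases
    ins_ev = next(e for e in events if e.kind == "ins")
    assert ins_ev.read_base == "T" and ins_ev.qv == 80


def test_gap_run_counting_mode():
    # a 3-base deletion: 3 events per-base, 1 event per-run
    read = make_read(sequence="ACAC",
                     cigar=[("M", 2), ("D", 3), ("M", 2)])
    ref = "ACGTGAC"
    assert len(pf.classify_errors(read, ref)) == 3
    assert len(pf.classify_errors(read, ref, gap_events="per-run")) == 1


def test_reverse_strand_events_complemented_for_tally():
    ev = pf.ErrorEvent("sub", 10, "G", "A", 93, "-")
    assert ev.strand_oriented() == ("C", "T")
    counts = pf.ErrorCounts()
    counts.add_event(ev)
    assert counts.subs[("C", "T")] == 1


def test_planted_events_recovered_against_truth(plain_amplicon):
    """Simulator truth oracle: every planted substitution, deletion and
    insertion reappears in classification, in kind and count."""
    cfg = pf.SimulationConfig(seed=21, sub_rate_per_doubling=3e-3,
                              del_rate_per_doubling=1e-3,
                              ins_rate_per_doubling=5e-4,
                              target_doublings=10, n_reads=300)
    reads, truth = pf.simulate_amplification(plain_amplicon, cfg)
    counts, events = pf.count_errors(reads, plain_amplicon.references())
    for kind, got in (("sub", counts.n_substitutions),
                      ("del", counts.n_deletion),
                      ("ins", counts.n_insertion)):
        want = sum(1 for rec in truth for e in rec.events if e.kind == kind)
        assert got == want


# ---------------------------------------------------------------------------
# rates


def test_substitution_rate_hand_example():
    counts = _counts(n_a=1000, n_t=1000, n_g=500, n_c=500,
                     subs={"A>G": 2, "C>T": 1})
    e_at, e_gc, e_sub = pf.substitution_rate(counts)
    assert e_at == pytest.approx(2 / 2000)
    assert e_gc == pytest.approx(1 / 1000)
    assert e_sub == pytest.approx(1e-3)


def test_zero_substitutions_rate_zero():
    counts = _counts(n_a=250_000, n_t=250_000, n_g=250_000, n_c=250_000)
    assert pf.substitution_rate(counts, "plain") == 0.0
    assert pf.substitution_rate(counts)[2] == 0.0


def test_composition_averaging_equals_plain_when_balanced():
    # N_A+N_T == N_G+N_C and symmetric events: the two conventions coincide
    counts = _counts(n_a=1000, n_t=1000, n_g=1000, n_c=1000,
                     subs={"A>G": 3, "T>C": 3, "G>A": 3, "C>T": 3})
    assert pf.substitution_rate(counts)[2] == \
        pytest.approx(pf.substitution_rate(counts, "plain"))


def test_undefined_rates_raise():
    empty = pf.ErrorCounts()
    with pytest.raises(UndefinedRateError):
        pf.substitution_rate(empty)
    with pytest.raises(UndefinedRateError):
        pf.indel_rates(empty)
    with pytest.raises(UndefinedRateError):
        pf.mutational_spectrum(empty)


def test_indel_rates_arithmetic():
    counts = _counts(n_a=2_500_000, n_t=2_500_000, n_g=2_500_000,
                     n_c=2_500_000, n_del=24, n_ins=0)
    e_del, e_ins = pf.indel_rates(counts)
    assert e_del == pytest.approx(2.4e-6)
    assert e_ins == 0.0


def test_doublings_from_yield():
    assert pf.doublings_from_yield(100, 100) == 0.0
    assert pf.doublings_from_yield(1024, 1) == pytest.approx(10.0)
    assert pf.doublings_from_yield(1500, 100) == pytest.approx(math.log2(15))
    with pytest.raises(UndefinedRateError):
        pf.doublings_from_yield(50, 100)
    with pytest.raises(UndefinedRateError):
        pf.doublings_from_yield(100, 0)


def test_normalize_examples():
    assert pf.normalize_per_doubling(0.0, 10) == 0.0
    assert pf.normalize_per_doubling(1e-3, 10) == pytest.approx(2e-4)
    with pytest.raises(UndefinedRateError):
        pf.normalize_per_doubling(1e-3, 0)


@given(st.floats(1e-9, 1e-2), st.floats(0.1, 30))
def test_propagation_roundtrip_identity(e, n):
    """normalize(propagate(e, n), n) == e for any e, n > 0."""
    assert pf.normalize_per_doubling(pf.propagate(e, n), n) == \
        pytest.approx(e, rel=1e-12)


def test_per_cycle_rate():
    assert pf.round_sig(pf.per_cycle_rate(2.3e-5, 16), 2) == \
        pytest.approx(1.4e-6)
    assert pf.per_cycle_rate(0.0, 16) == 0.0
    assert pf.per_cycle_rate(1.6e-3, 16) == pytest.approx(1e-4)
    with pytest.raises(UndefinedRateError):
        pf.per_cycle_rate(1e-3, 0)


# ---------------------------------------------------------------------------
# spectrum


def test_spectrum_single_pair():
    counts = _counts(n_a=1000, n_t=1000, n_g=1000, n_c=1000,
                     subs={"A>G": 10, "T>C": 5})
    table = pf.mutational_spectrum(counts)
    assert table.pair_percent["A>G/T>C"] == pytest.approx(100.0)


def test_spectrum_hand_tally():
    subs = {"A>G": 33, "T>C": 33, "G>A": 19, "A>T": 9,
            "A>C": 2, "G>C": 2, "G>T": 2}
    counts = _counts(n_a=1000, n_t=1000, n_g=1000, n_c=1000, subs=subs)
    table = pf.mutational_spectrum(counts)
    total = sum(subs.values())
    assert table.pair_percent["A>G/T>C"] == pytest.approx(100 * 66 / total)
    assert table.pair_percent["G>A/C>T"] == pytest.approx(100 * 19 / total)
    assert sum(table.pair_percent.values()) == pytest.approx(100.0, abs=0.1)


def test_summary_accuracy_is_inverse_rate():
    counts = _counts(n_a=1000, n_t=1000, n_g=1000, n_c=1000,
                     subs={"A>G": 4, "C>T": 4})
    summary = pf.summarize_rates(counts, n=10)
    assert summary.accuracy == pytest.approx(1 / summary.e_normalized)


# ---------------------------------------------------------------------------
# parameter recovery


@pytest.mark.parametrize("e", [5e-7, 5e-6, 1.5e-4, 5e-4])
def test_substitution_rate_recovery(e, plain_amplicon):
    """Configured per-doubling substitution rates across four decades are
    recovered within 3 binomial standard errors."""
    n = 10
    cfg = pf.SimulationConfig(seed=int(e * 1e9) % 100_000,
                              sub_rate_per_doubling=e, target_doublings=n,
                              n_reads=4000)
    reads, _ = pf.simulate_amplification(plain_amplicon, cfg)
    counts, _ = pf.count_errors(reads, plain_amplicon.references())
    _, _, f = pf.substitution_rate(counts)
    estimate = pf.normalize_per_doubling(f, n)
    expected_events = pf.propagate(e, n) * counts.n_total
    se = 2 / n * math.sqrt(expected_events) / counts.n_total
    assert abs(estimate - e) < 3 * se + 1e-12
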