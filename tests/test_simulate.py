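import math

import numpy as np
import pytest

import pcrfidelity as pf
from pcrfidelity.dna import revcomp, seq_array
from pcrfidelity.exceptions import ConfigError


def _truth_count(truth, kind):
    return sum(1 for rec in truth for ev in rec.events if ev.kind == kind)


def test_zero_rate_simulation_is_faithful(plain_amplicon):
    cfg = pf.SimulationConfig(seed=1, target_doublings=10, n_reads=50)
    reads, truth = pf.simulate_amplification(plain_amplicon, cfg)
    template = plain_amplicon.entries[0].sequence
    assert all(r.sequence == template for r in reads)
    assert all(not rec.events for rec in truth)


def test_conflicting_mode_rejected():
    with pytest.raises(ConfigError):
        pf.SimulationConfig(seed=1, efficiency_per_cycle=0.9,
                            target_doublings=10)
    with pytest.raises(ConfigError):
        pf.SimulationConfig(seed=1)


def test_bad_spectrum_named_in_error():
    with pytest.raises(ConfigError) as exc:
        pf.SimulationConfig(seed=1, target_doublings=10,
                            sub_spectrum=np.full(12, 0.9 / 12))
    assert any("sub_spectrum" in path for path, _ in exc.value.problems)


def test_closed_form_poisson_mean(plain_amplicon):
    """Raw error load follows the propagation model: mean substitutions per
    read = n*e/2*L (Poisson), here 10*2e-4/2*1100 = 1.1."""
    cfg = pf.SimulationConfig(seed=2, sub_rate_per_doubling=2e-4,
                              target_doublings=10, n_reads=50_000)
    reads, truth = pf.simulate_amplification(plain_amplicon, cfg)
    expected = 10 * 2e-4 / 2 * 1100
    observed = _truth_count(truth, "sub") / len(reads)
    se = math.sqrt(expected / len(reads))
    assert abs(observed - expected) < 3 * se


def test_lineage_perfect_efficiency_doublings(plain_amplicon):
    """Efficiency 1.0 over 4 cycles turns 1 molecule into 16: log2(16) = 4."""
    cfg = pf.SimulationConfig(seed=3, efficiency_per_cycle=1.0, n_cycles=4,
                              initial_molecules=1, n_reads=10)
    pf.simulate_amplification(plain_amplicon, cfg)
    assert pf.simulate_amplification.last_doublings == pytest.approx(4.0)


def test_closed_form_and_lineage_agree(plain_amplicon):
    """Both simulator modes produce the same raw per-base substitution
    fraction for the same (e, n); tolerance covers 3 standard errors
    including lineage-correlation overdispersion."""
    e, cycles = 1e-3, 8
    lin = pf.SimulationConfig(seed=4, sub_rate_per_doubling=e,
                              efficiency_per_cycle=1.0, n_cycles=cycles,
                              initial_molecules=64, n_reads=20_000)
    reads_l, truth_l = pf.simulate_amplification(plain_amplicon, lin)
    assert pf.simulate_amplification.last_doublings == pytest.approx(cycles)
    clo = pf.SimulationConfig(seed=5, sub_rate_per_doubling=e,
                              target_doublings=cycles, n_reads=20_000)
    reads_c, truth_c = pf.simulate_amplification(plain_amplicon, clo)
    f_l = _truth_count(truth_l, "sub") / (len(reads_l) * 1100)
    f_c = _truth_count(truth_c, "sub") / (len(reads_c) * 1100)
    assert f_c == pytest.approx(cycles * e / 2, rel=0.05)
    assert f_l == pytest.approx(f_c, rel=0.08)


def test_truth_matches_observable_mismatches(plain_amplicon):
    """Conservation: for indel-free reads the number of truth substitution
    events equals the Hamming distance between read and template."""
    cfg = pf.SimulationConfig(seed=6, sub_rate_per_doubling=5e-3,
                              target_doublings=10, n_reads=500)
    reads, truth = pf.simulate_amplification(plain_amplicon, cfg)
    template = seq_array(plain_amplicon.entries[0].sequence)
    for read, rec in zip(reads, truth):
        mism = int(np.count_nonzero(seq_array(read.sequence) != template))
        assert mism == len(rec.events)


def test_spectrum_fidelity_chisquare(plain_amplicon):
    """Empirical directed-substitution frequencies converge to the configured
    spectrum (chi-square goodness of fit, ~100k events)."""
    from scipy import stats
    cfg = pf.SimulationConfig(seed=7, sub_rate_per_doubling=1e-3,
                              target_doublings=10, n_reads=20_000)
    reads, _ = pf.simulate_amplification(plain_amplicon, cfg)
    counts, _ = pf.count_errors(reads, plain_amplicon.references())
    from pcrfidelity.dna import SUBSTITUTIONS
    observed = np.array([counts.subs[p] for p in SUBSTITUTIONS])
    total = observed.sum()
    assert total > 80_000
    # expected shares must account for template composition: events are drawn
    # type-first, then placed on a source-matching base, so on this
    # near-balanced template the configured spectrum is the expectation
    expected = cfg.sub_spectrum * total
    _, p = stats.chisquare(observed, expected)
    assert p > 0.01


def test_damage_accumulation_no_replication(plain_amplicon):
    """With damage rate d over c cycles and no replication the mutated
    per-base fraction approaches 1-(1-d)^c ~= c*d."""
    d, c = 1e-5, 16
    cfg = pf.SimulationConfig(seed=8, damage_rate_per_cycle=d, n_cycles=c,
                              target_doublings=0.0, n_reads=20_000)
    reads, truth = pf.simulate_amplification(plain_amplicon, cfg)
    bases = len(reads) * 1100
    observed = _truth_count(truth, "damage") / bases
    expected = 1 - (1 - d) ** c
    se = math.sqrt(expected / bases)
    assert abs(observed - expected) < 3 * se


def test_make_inversion_read_classes(structured_set):
    template = structured_set.entries[0].sequence
    element = structured_set.elements[0]
    s, e, st = element.s0, element.e0, element.stem_length
    assert pf.make_inversion_read(template, element, "correct") == template
    double = pf.make_inversion_read(template, element, "double")
    diffs = [i for i, (x, y) in enumerate(zip(double, template)) if x != y]
    assert diffs and min(diffs) >= s + st and max(diffs) < e - st
    assert double[s + st:e - st] == revcomp(template[s + st:e - st])
    with pytest.raises(ValueError):
        pf.make_inversion_read(template, element, "sideways")


def test_single_switch_product_length_227(structured_set):
    """The 5'-anchored single-switch fold-back product of the stem-10 element
    at 45..183 on a 1353-nt amplicon is 227 nt — too short to sequence on
    the original instrument, which is why that class went undetected."""
    template = structured_set.entries[0].sequence
    element = structured_set.elements[0]
    product = pf.make_inversion_read(template, element, "single-top")
    assert len(product) == 227
    bottom = pf.make_inversion_read(template, element, "single-bottom")
    assert len(bottom) == (1353 - element.e0) + (1353 - element.s0)


def test_emit_reads_roundtrip(tmp_path, plain_amplicon):
    cfg = pf.SimulationConfig(seed=9, sub_rate_per_doubling=2e-3,
                              del_rate_per_doubling=5e-4,
                              ins_rate_per_doubling=5e-4,
                              target_doublings=10, n_reads=100)
    reads, truth = pf.simulate_amplification(plain_amplicon, cfg)
    paths = pf.emit_reads(reads, truth, pf.product_references(plain_amplicon),
                          tmp_path)
    back = pf.read_sam(paths["reads_sam"])
    assert len(back) == len(reads)
    template = plain_amplicon.entries[0].sequence
    for orig, loaded in zip(reads, back):
        assert loaded.sequence == orig.sequence
        assert loaded.cigar == orig.cigar
        assert loaded.n_passes == orig.n_passes
        assert loaded.strand == orig.strand
        # the CIGAR must reconstruct the read from the reference exactly
        rebuilt = []
        qpos, rpos = 0, loaded.ref_start
        for op, n in loaded.cigar:
            if op == "M":
                rebuilt.append(loaded.sequence[qpos:qpos + n])
                qpos += n
                rpos += n
            elif op == "D":
                rpos += n
            elif op == "I":
                rebuilt.append(loaded.sequence[qpos:qpos + n])
                qpos += n
        assert "".join(rebuilt) == loaded.sequence


def test_emit_zero_reads_valid_files(tmp_path, plain_amplicon):
    paths = pf.emit_reads([], [], pf.product_references(plain_amplicon),
                          tmp_path)
    assert pf.read_sam(paths["reads_sam"]) == []
    assert paths["reads_fasta"].exists()
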