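# pcrfidelity

Analysis of the error pathways of the Polymerase Chain Reaction as seen by
strand-specific single-molecule consensus sequencing, paired with a PCR
simulator that produces every read class the analysis must detect — with
recorded ground truth, so the whole pipeline is verifiable by parameter
recovery without any sequencing data.

## What it measures

PCR introduces several distinct kinds of errors into amplification
products, and all of them end up in downstream sequencing data:

* **Polymerase base substitutions and indels.** The observed error fraction
  *f* after amplification grows linearly with the number of effective
  template doublings *n* = log₂(*Y*/*I*) (yield over input):
  *f* = *n·e*/2, so the per-doubling polymerase rate is recovered as
  *e* = *f*·2/*n*. Substitution rates are composition-averaged
  (*e*\_AT and *e*\_GC computed separately over A/T and G/C source bases,
  then averaged) and the spectrum is tallied over the six complementary
  substitution pairs (A→G/T→C, G→A/C→T, …).
* **Thermocycling DNA damage.** Heating alone mutates DNA (cytosine
  deamination read as C→T on the damaged strand); the package recovers the
  per-cycle damage rate and the directed C→T excess, which is visible only
  because events are tallied in sequenced-strand orientation.
* **Template-switching at inverted repeats ("inversions").** At
  cruciform-forming elements the polymerase can cross between strands,
  producing reads with a reverse-complemented loop (double switch) or
  truncated fold-back molecules (single switches). Reads are classified
  against four constructed references per element with a >95%-coverage,
  zero-mismatch rule.
* **PCR-mediated recombination.** Co-amplified homologs differing at
  single-base markers yield chimeric strands; switches are counted as
  transitions between consecutive valid marker calls, doubled to account
  for cryptic (same-template) events, and normalized per doubling:
  rate = (2·*N*\_re/*N*\_total)·2/*n*.

The simulator supports a closed-form mode (per-read Poisson event counts at
the propagation-model means) and an explicit branching-process lineage mode
(per-cycle replication with inherited errors), and the two agree — the
*f* = *n·e*/2 behaviour *emerges* from the lineage simulation.

## Worked example

`examples/substitution_rates.py` simulates a low-fidelity polymerase
(1.5×10⁻⁴ sub/base/doubling, 10 doublings, 1.1-kb equimolar amplicon,
20,000 consensus reads), filters, classifies and normalizes:

```
analyzed bases        : 22,000,000
substitution events   : 16,449
raw fraction f        : 7.384e-04
e per doubling (f*2/n): 1.477e-04   (configured 1.5e-04)
accuracy (1/e)        : 6,771 bases per error
spectrum (% of substitutions):
  A>G/T>C     66.1
  G>A/C>T     19.1
  A>T/T>A      9.6
  ...
```

The raw fraction (7.4×10⁻⁴) is the error load a naive count would report;
dividing out error propagation recovers the configured per-doubling rate
within sampling error, and the spectrum tally reproduces the configured
transition-dominated pattern. The other examples cover inversion scanning
(`inversion_scan.py`), recombination (`recombination_rate.py`) and damage
(`thermocycling_damage.py`); each prints the recovered quantity next to the
value it was configured with.

The same stages are scriptable from a shell:

```
pcr-fidelity run --config examples/demo-config.yaml --out demo-out
```

which writes reads (FASTA/SAM with ground-truth alignments), filter audits,
and rate/spectrum/inversion/recombination tables as JSON+TSV twins, plus a
manifest; identical config and seed reproduce identical reports
byte-for-byte.

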