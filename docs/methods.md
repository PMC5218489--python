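# Methods

## The propagation model

All per-doubling rates rest on the linear error-propagation model for
exponential amplification. An error made in an early cycle is copied into
every descendant strand; averaging over the cycle of origin, the expected
per-base error fraction after amplification is

    f = n · e / 2,

where `e` is the per-base, per-doubling event rate and
`n = log2(yield/input)` the number of effective doubling events (always at
most the cycle count, since per-cycle replication efficiency is below one).
Estimators invert this: `e = f·2/n`. The model is first-order; the
closed-form simulator warns when `n·e ≥ 0.1`, where the linearization
becomes visibly biased.

`n` in real experiments is yield-derived and rarely published alongside
rate tables; all recovery tests therefore control `n` in simulation rather
than reconstructing it. The default `target_doublings = 10.7` is the value
implied by the published recombination counts (raw 5.13×10⁻⁴ against a
normalized 9.6×10⁻⁵), i.e. a 16-cycle reaction at roughly 67% effective
per-cycle yield, which is a typical end-point PCR.

## Substitution rates and spectrum

Raw substitution rates are composition-averaged:

    e_AT = (N_subs from A + N_subs from T) / (N_A + N_T)
    e_GC = (N_subs from G + N_subs from C) / (N_G + N_C)
    e_sub = (e_AT + e_GC) / 2

which makes the estimate independent of amplicon base composition. The
G/C-numerator of the printed source formula lists an A→T term where C→T is
plainly intended (the A→T change is already counted in the A/T numerator,
and the G/C numerator would otherwise omit the most common damage change);
this package implements C→A, C→G, C→T and flags the deviation here rather
than silently "fixing" the source. Plain division (total substitutions /
total bases) is used for plasmid background samples, matching practice.

Denominators count analyzed reference bases of aligned (`M`) segments of
surviving reads, summed over reads — bases read multiple times count
multiply, consistent with per-base rate semantics. Primer intervals and
engineered marker positions are excluded symmetrically: events there are
masked *and* the masked bases leave the denominator. (Marker exclusion
matters in co-amplification runs, where a recombinant read's marker alleles
would otherwise masquerade as substitutions.)

**Orientation convention.** Directed substitution counts are tallied in the
orientation of the sequenced strand: events on reverse-strand consensus
reads are complemented before entering the 12-bin directed table. This is
what makes single-strand chemistry observable — cytosine deamination is
C→T on the damaged strand, and a reference-orientation tally would split it
50:50 between C→T and G→A. The six complementary-pair table
(A→G/T→C, …) is invariant to this choice. Multi-base gaps count one event
per deleted reference base / inserted read base.

## Read and event filters

Two presets reflect the two analysis regimes:

* rates: ≥15 consensus passes, MAPQ = 254, read length ≥80% of the expected
  amplicon, chimeric reads dropped, event QV = 93 required, primer masking
  on. The length criterion uses the consensus-read length (not aligned
  length); both are available in the audit.
* switching (inversions/recombination): ≥3 passes and nothing else — the
  products being detected are legitimately shorter (227-nt fold-backs) or
  longer than the amplicon, so a length cut would censor the signal.

A deletion has no read base; its event QV is taken as the minimum QV of the
two flanking read bases (the source is silent on this; configurable).
Removed reads are attributed to the first failing criterion in the order
passes → mapq → length → chimeric; survivorship itself is a conjunction and
order-independent.

## Inversion geometry and classification

An inverted-repeat element `start..end` (1-based, inclusive) with stem `s`
and loop `l` satisfies `end−start+1 = 2s+l`, with the first `s` bases the
reverse complement of the last `s`. Replication products:

* **correct** — the faithful product;
* **double** — the loop reverse-complemented in place (crossing to the
  opposite strand at one stem and back at the other; the stems themselves
  pair, so the crossover inside them is invisible);
* **single-top / single-bottom** — one crossover without return: the
  product follows the reference up to the element, traverses it on the
  opposite strand and folds back toward the end it started from. In
  0-based template coordinates with element `[s0, e0)`:
  `single-top = T[0:s0] + revcomp(T[0:e0])` (5'-anchored) and
  `single-bottom = revcomp(T[e0:]) + T[s0:]` (3'-anchored).

For the stem-10 element at 45..183 of a 1353-nt amplicon the 5'-anchored
product is 44 + 183 = 227 nt — short enough to explain why that class goes
undetected on instruments with a lower size cutoff; the report notes this
length censoring. (The published element table gives that element's span as
139 nt with stem 10 but prints loop 129; 2·10+129 = 149 contradicts the
span, and the 227-nt product confirms the span, so loop 119 is used.)

Each element's four classification references consist of the element as it
appears in the product plus up to 30 adjacent nucleotides per available
side. A read is assigned the label of the *unique* reference it contains
with more than 95% coverage and zero mismatches (both read orientations
tried; truncated coverage honoured only at read ends). Exact matching is
essential: for small elements the correct and double references differ by
only a couple of bases, so any mismatch tolerance would conflate classes.
Ambiguous double-matches are unassigned. The reported percentage uses all
scanned reads as denominator.

## Recombination

Marker calls require the read base to equal one allele and the two flanking
bases on each side to be aligned and match the shared reference; deleted or
mismatching context gives `invalid`. Switches are transitions between
consecutive *valid* calls — a transition across an invalid marker counts
once, localized to the interval between the flanking valid markers. (A
strict mode discarding reads with any invalid marker exists as an
alternative reading of the source, off by default.) Vectors with fewer than
two valid calls contribute bases to `N_total` but cannot contribute events,
a small censoring toward zero.

The raw rate is `2·N_re/N_total` with `N_total` the summed consensus length
of analyzed reads. The factor 2 assumes a 50:50 template mix, in which half
of all switches land on an indistinguishable template copy (cryptic) —
verified in simulation, where mixing two *identical* sequences yields zero
detected events while truth events continue. Normalization per doubling
then applies `·2/n`. Known small biases of the detector, both quantified in
tests: switches outside the first/last marker are undetectable (markers are
end-anchored ~5 bp from the template ends, keeping this ≈1%), and an even
number of effective switches within one interval cancels (≈2% at the
published event load).

## The simulator

**Closed-form mode** draws per-read event counts from Poisson distributions
with per-base means `n·e/2` for each per-doubling rate and `c·d` for damage
(`c` thermal cycles at per-cycle rate `d`; the no-replication mock-cycling
convention, expected mutated fraction `1−(1−d)^c ≈ c·d`). Event identities
are drawn type-first from the 12-weight directed spectrum, then placed
uniformly among bases carrying the source base — equivalent to a uniform
per-base process on the equimolar templates used throughout, and the reason
empirical spectra converge to the configured one. Identities are drawn in
molecule-local orientation (a bottom-strand C→T appears as G→A in reference
orientation). Point events occupy distinct positions, and deletions avoid
them, so every planted event stays observable (truth-conservation is tested
exactly). Default read quality is the maximum (QV 93, MAPQ 254) with pass
counts uniform in a configured range, so synthetic reads pass filters
unless a test degrades them deliberately.

**Lineage mode** is an explicit branching process: each cycle every strand
replicates with probability `efficiency_per_cycle`; the copy inherits its
parent's mosaic and events and acquires new ones at the per-doubling rates;
damage strikes every molecule every cycle; reads are sampled (with
replacement) from the final pool and `n = log2(final/initial)` is exposed
for normalization. Error positions are drawn against the ancestral template
index (mutation density is far too low for compounding to matter).
Propagation behaviour is emergent here, and the two modes agree within
sampling error at equal `(e, n)` — lineage reads are ancestrally
correlated, so agreement tolerances include that overdispersion. Whether
template-switching reads arise in one replication pass or across cycles is
mechanistically open; both modes exist precisely so neither story is
asserted.

Recombination switch events pick the partner uniformly among co-amplified
homologs (including the current one — those are the cryptic events) and
complete the read on the partner; multiple switches per read are allowed.
Inversion-class products are emitted noise-free in both modes: stacked
substitutions on a truncated fold-back have no well-defined template
coordinate, the zero-mismatch classifier would discard them anyway, and
switching percentages are scored on unfiltered reads.

**What the generator does not emulate:** consensus miscalls (quality is
ideal unless degraded), alignment artifacts and homopolymer-indel noise,
polymerase pausing kinetics and thermodynamic cruciform stability,
cycle-dependent efficiency decline, and recombination among more than two
homolog families. Passing recovery tests therefore demonstrates estimator
correctness under the stated event models — not robustness to consensus or
alignment noise in real data.

## Numerical conventions

Internal coordinates are 0-based half-open; all file formats and reports
are 1-based inclusive. One master seed drives every stochastic draw through
a single generator (closed-form draws are vectorised per read in a fixed
order), so runs are reproducible bit-for-bit; reports contain no
timestamps and re-running a config+seed reproduces them byte-for-byte.
Rates are reported to 2 significant figures in text reports. Undefined
rates (zero denominators, zero-substitution spectra) raise typed errors
rather than returning NaN. Artificial templates are drawn equimolar (each
base 25% ± 5 pp) with homopolymer runs capped at 5 bases; homolog markers
are placed at near-regular intervals anchored ~5 bp from both ends (layout
is a design choice: it keeps the switch-detectable span close to the full
molecule). Problem sizes in tests (2–50 k reads) and the acceptance script
(20–200 k reads) are chosen so binomial 3-standard-error bands sit well
inside the tolerances being checked.
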