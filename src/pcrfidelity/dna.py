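"""Small DNA-string utilities used throughout the package.

Sequences are plain upper-case ``str`` over A/C/G/T. Internally all
coordinates are 0-based half-open; file formats and reports are 1-based
inclusive.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: The 12 directed substitutions in canonical order (source, target).
SUBSTITUTIONS: tuple[tuple[str, str], ...] = tuple(
    (a, b) for a in BASES for b in BASES if a != b
)
SUB_INDEX = {pair: i for i, pair in enumerate(SUBSTITUTIONS)}

#: The six complementary substitution pairs used for spectrum tables,
#: ordered as in standard polymerase-fidelity reports.
SPECTRUM_PAIRS: tuple[tuple[tuple[str, str], tuple[str, str]], ...] = (
    (("A", "G"), ("T", "C")),
    (("G", "A"), ("C", "T")),
    (("A", "T"), ("T", "A")),
    (("A", "C"), ("T", "G")),
    (("G", "C"), ("C", "G")),
    (("G", "T"), ("C", "A")),
)


def pair_label(pair) -> str:
    (a, b), (c, d) = pair
    return f"{a}>{b}/{c}>{d}"


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def max_homopolymer(seq: str) -> int:
    """Length of the longest single-base run in ``seq``."""
    if not seq:
        return 0
    best = run = 1
    prev = seq[0]
    for ch in seq[1:]:
        if ch == prev:
            run += 1
            if run > best:
                best = run
        else:
            run = 1
            prev = ch
    return best


def seq_array(seq: str) -> np.ndarray:
    """View a sequence as a uint8 array for vectorised comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def base_composition(seq: str) -> dict[str, int]:
    arr = seq_array(seq)
    return {b: int(np.count_nonzero(arr == ord(b))) for b in BASES}


def random_sequence(length: int, rng: np.random.Generator,
                    max_run: int = 5, max_tries: int = 200) -> str:
    """Random near-equimolar sequence with homopolymer runs capped at ``max_run``.

    Emulates artificial amplicon design: each base frequency within 0.05 of
    0.25 and no run longer than ``max_run`` bases.
    """
    for _ in range(max_tries):
        chars = rng.integers(0, 4, size=length)
        seq = "".join(BASES[i] for i in chars)
        # break long runs in place rather than rejecting the whole draw
        out = list(seq)
        run_start = 0
        for i in range(1, length + 1):
            if i == length or out[i] != out[run_start]:
                run_len = i - run_start
                if run_len > max_run:
                    for j in range(run_start + max_run, i, max_run + 1):
                        choices = [b for b in BASES if b != out[j]
                                   and (j + 1 >= length or b != out[j + 1])
                                   and (j == 0 or b != out[j - 1])]
                        out[j] = choices[int(rng.integers(len(choices)))]
                run_start = i
        seq = "".join(out)
        comp = base_composition(seq)
        if max_homopolymer(seq) <= max_run and all(
                abs(comp[b] / length - 0.25) <= 0.05 for b in BASES):
            return seq
    raise RuntimeError("could not generate a constraint-satisfying sequence")
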