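"""Independent brute-force oracles used to cross-check the implementation.

Everything here counts with plain Python dictionaries/loops, deliberately
sharing no code path with the vectorised encoders (only the frozen ordering
constants, which are a documented convention, not logic).
"""

from collections import Counter

import numpy as np

from orfsvm.features import AA_ORDER, CODONS, GENETIC_CODE, NUCLEOTIDES

DINTS = [a + b for a in NUCLEOTIDES for b in NUCLEOTIDES]
DIAAS = [a + b for a in AA_ORDER for b in AA_ORDER]
DICODONS_INDEX = {a + b: i for i, (a, b) in enumerate(
    (a, b) for a in CODONS for b in CODONS
)}


def split_codons(seq):
    seq = seq.upper()
    return [seq[i : i + 3] for i in range(0, len(seq) // 3 * 3, 3)]


def is_valid(codon):
    return all(b in NUCLEOTIDES for b in codon)


def _freqs(counter, order):
    total = sum(counter.values())
    if total == 0:
        return np.zeros(len(order))
    return np.array([counter[k] / total for k in order])


def mono_nt(seq):
    cods = [c for c in split_codons(seq) if is_valid(c)]
    parts = [_freqs(Counter(c[p] for c in cods), NUCLEOTIDES) for p in range(3)]
    return np.concatenate(parts)


def _codon_pairs(seq, step=3):
    cods = split_codons(seq)
    idxs = range(len(cods) - 1) if step == 3 else range(0, len(cods) - 1, 2)
    return [
        (cods[i], cods[i + 1])
        for i in idxs
        if is_valid(cods[i]) and is_valid(cods[i + 1])
    ]


def di_nt(seq):
    cods = [c for c in split_codons(seq) if is_valid(c)]
    g12 = _freqs(Counter(c[0] + c[1] for c in cods), DINTS)
    g23 = _freqs(Counter(c[1] + c[2] for c in cods), DINTS)
    pairs = _codon_pairs(seq, step=3)
    g31 = _freqs(Counter(a[2] + b[0] for a, b in pairs), DINTS)
    return np.concatenate([g12, g23, g31])


def codon(seq):
    cods = [c for c in split_codons(seq) if is_valid(c)]
    return _freqs(Counter(cods), CODONS)


def dicodon(seq, step=3):
    pairs = _codon_pairs(seq, step)
    out = np.zeros(4096)
    if pairs:
        cnt = Counter(a + b for a, b in pairs)
        for hexamer, n in cnt.items():
            out[DICODONS_INDEX[hexamer]] = n / len(pairs)
    return out


def amino(seq):
    cods = [c for c in split_codons(seq) if is_valid(c)]
    return _freqs(Counter(GENETIC_CODE[c] for c in cods), list(AA_ORDER))


def diaa(seq, step=3):
    pairs = _codon_pairs(seq, step)
    return _freqs(
        Counter(GENETIC_CODE[a] + GENETIC_CODE[b] for a, b in pairs), DIAAS
    )


ORACLES = {1: mono_nt, 2: di_nt, 3: codon, 4: dicodon, 5: amino, 6: diaa}


def random_dna(rng, length, with_ambiguous=False, with_lowercase=False):
    alphabet = list("ACGT")
    probs = [0.25] * 4
    if with_ambiguous:
        alphabet = list("ACGTN")
        probs = [0.24, 0.24, 0.24, 0.24, 0.04]
    seq = "".join(rng.choice(alphabet, size=length, p=probs))
    if with_lowercase:
        chars = list(seq)
        for i in rng.choice(length, size=max(1, length // 10), replace=False):
            chars[i] = chars[i].lower()
        seq = "".join(chars)
    return seq


def reverse_complement(seq):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq.upper()))


def uncovered_mask(genome_len, intervals):
    """Per-base boolean mask: True where no 1-based inclusive interval covers."""
    mask = np.ones(genome_len, dtype=bool)
    for s, e in intervals:
        mask[s - 1 : e] = False
    return mask
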