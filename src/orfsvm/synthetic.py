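"""Labeled synthetic benchmark sequences with controllable coding signal.

Coding sequences are ATG + i.i.d. sense codons drawn from a codon usage
table + a terminal stop, so they never contain internal in-frame stops and
their lengths are divisible by 3.  Non-coding sequences are i.i.d. bases at
a configurable GC fraction with no frame structure, with lengths above the
usual 300 bp negative-set threshold by default and deliberately not rounded
to codon multiples (exercising the encoders' truncation rule).

Three shipped signal levels:

* ``strong``: a heavily biased codon table (guanine-leading, A/T-ending
  codons strongly preferred) against a uniform-composition background —
  near-separable by construction.
* ``yeast_like``: a moderately biased table at coding GC around 0.40
  (packaged in ``data/yeast_like_codons.yaml``; the values are illustrative
  defaults, not measured usage) against a background at GC 0.36.
* ``null``: both classes drawn from the same frame-free base-composition
  model, only the labels differ — any classifier should sit near 50%
  balanced accuracy.  (A start/stop-scaffolded "coding" null would leak the
  absence of internal stop codons, which is itself a strong coding signal,
  so the null deliberately drops the ORF scaffold.)

All sampling flows from a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .annotation_io import LabeledSequence, write_fasta, write_label_table
from .features import CODONS, GENETIC_CODE

__all__ = [
    "STOP_CODONS",
    "SENSE_CODONS",
    "CodingModel",
    "NoncodingModel",
    "BenchmarkSet",
    "sample_coding",
    "sample_noncoding",
    "make_benchmark",
    "gc_contrast_benchmark",
    "yeast_like_codon_table",
    "tilted_codon_table",
    "write_benchmark",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(c for c in CODONS if GENETIC_CODE[c] != "*")  # 61 codons


@dataclass(frozen=True)
class CodingModel:
    """Generative model for coding-like ORFs.

    codon_probs: usage over the 61 sense codons (must sum to 1; any stop
    codon present with nonzero probability is a configuration error).
    length_range: inclusive range of *body* codon counts; the emitted
    sequence is ATG + body + stop, so its bp length is 3*(body+2).
    """

    codon_probs: dict[str, float]
    stop_probs: dict[str, float] = field(
        default_factory=lambda: {"TAA": 0.5, "TAG": 0.25, "TGA": 0.25}
    )
    length_range: tuple[int, int] = (99, 198)

    def __post_init__(self) -> None:
        for codon, p in self.codon_probs.items():
            if codon in STOP_CODONS and p > 0:
                raise ValueError(f"stop codon {codon} with nonzero internal probability")
            if codon not in CODONS:
                raise ValueError(f"not a codon: {codon!r}")
        total = sum(self.codon_probs.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"codon probabilities sum to {total}, not 1")
        if not np.isclose(sum(self.stop_probs.values()), 1.0, atol=1e-6):
            raise ValueError("stop probabilities must sum to 1")
        if self.length_range[0] < 0 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid codon-count range")


@dataclass(frozen=True)
class NoncodingModel:
    """Frame-free i.i.d. base model at a given GC fraction."""

    gc: float = 0.36
    length_range: tuple[int, int] = (301, 900)  # bp, inclusive

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length range")

    @property
    def base_probs(self) -> np.ndarray:
        """Probabilities over A, C, G, T (A=T and C=G symmetric)."""
        return np.array([(1 - self.gc) / 2, self.gc / 2, self.gc / 2, (1 - self.gc) / 2])


@dataclass(frozen=True)
class BenchmarkSet:
    sequences: tuple[LabeledSequence, ...]
    seed: int
    signal: str
    params: dict

    @property
    def positives(self) -> tuple[LabeledSequence, ...]:
        return tuple(s for s in self.sequences if s.label == 1)

    @property
    def negatives(self) -> tuple[LabeledSequence, ...]:
        return tuple(s for s in self.sequences if s.label == -1)


def sample_coding(
    model: CodingModel, n: int, seed: int, id_prefix: str = "cod"
) -> list[LabeledSequence]:
    """n coding-like ORFs: ATG + i.i.d. sense codons + one stop codon."""
    rng = np.random.default_rng(seed)
    codons = list(model.codon_probs.keys())
    probs = np.array([model.codon_probs[c] for c in codons])
    probs = probs / probs.sum()
    stops = list(model.stop_probs.keys())
    stop_p = np.array([model.stop_probs[s] for s in stops])
    stop_p = stop_p / stop_p.sum()
    lo, hi = model.length_range
    out = []
    for i in range(n):
        m = int(rng.integers(lo, hi + 1))
        body = rng.choice(len(codons), size=m, p=probs)
        stop = stops[int(rng.choice(len(stops), p=stop_p))]
        seq = "ATG" + "".join(codons[j] for j in body) + stop
        out.append(LabeledSequence(f"{id_prefix}_{i:05d}", seq, 1, "synthetic"))
    return out


def sample_noncoding(
    model: NoncodingModel, n: int, seed: int, id_prefix: str = "noncod"
) -> list[LabeledSequence]:
    """n frame-free i.i.d. sequences at the model's base composition."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    lo, hi = model.length_range
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(bases[rng.choice(4, size=length, p=model.base_probs)])
        out.append(LabeledSequence(f"{id_prefix}_{i:05d}", seq, -1, "synthetic"))
    return out


def tilted_codon_table(
    gc: float, tilt: float, lead_g_bonus: float = 0.0
) -> dict[str, float]:
    """Sense-codon table: composition background exponentially tilted toward
    A/T-ending codons (tilt > 0), optionally boosting G-leading codons.

    tilt = 0 reduces to the stop-free composition background at the given GC.
    """
    base_p = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    weights = {}
    for codon in SENSE_CODONS:
        w = base_p[codon[0]] * base_p[codon[1]] * base_p[codon[2]]
        pref = 1.0 if codon[2] in "AT" else -1.0
        w *= np.exp(tilt * pref)
        if codon[0] == "G":
            w *= np.exp(lead_g_bonus)
        weights[codon] = w
    total = sum(weights.values())
    return {c: w / total for c, w in weights.items()}


def yeast_like_codon_table() -> dict[str, float]:
    """The packaged moderately biased sense-codon table (illustrative values)."""
    with resources.files("orfsvm").joinpath("data/yeast_like_codons.yaml").open() as fh:
        table = yaml.safe_load(fh)
    return {str(k): float(v) for k, v in table["codon_probs"].items()}


def make_benchmark(
    n_pos: int, n_neg: int, signal: str = "yeast_like", seed: int = 0
) -> BenchmarkSet:
    """A labeled benchmark at one of the shipped signal levels."""
    rng = np.random.default_rng(seed)
    seed_pos = int(rng.integers(0, 2**31 - 1))
    seed_neg = int(rng.integers(0, 2**31 - 1))
    if signal == "strong":
        coding = CodingModel(
            codon_probs=tilted_codon_table(gc=0.5, tilt=2.0, lead_g_bonus=1.0),
            length_range=(99, 198),
        )
        noncoding = NoncodingModel(gc=0.5, length_range=(306, 600))
        pos = sample_coding(coding, n_pos, seed_pos)
        neg = sample_noncoding(noncoding, n_neg, seed_neg)
        params = {"coding_gc": 0.5, "tilt": 2.0, "noncoding_gc": 0.5}
    elif signal == "yeast_like":
        coding = CodingModel(
            codon_probs=yeast_like_codon_table(), length_range=(99, 198)
        )
        noncoding = NoncodingModel(gc=0.36, length_range=(303, 600))
        pos = sample_coding(coding, n_pos, seed_pos)
        neg = sample_noncoding(noncoding, n_neg, seed_neg)
        params = {"coding_gc": 0.40, "noncoding_gc": 0.36}
    elif signal == "null":
        background = NoncodingModel(gc=0.36, length_range=(303, 600))
        pos = [
            LabeledSequence(s.seq_id.replace("noncod", "cod"), s.sequence, 1, "synthetic")
            for s in sample_noncoding(background, n_pos, seed_pos)
        ]
        neg = sample_noncoding(background, n_neg, seed_neg)
        params = {"gc": 0.36, "note": "both classes from one base model"}
    else:
        raise ValueError(f"unknown signal level {signal!r} (strong|yeast_like|null)")
    return BenchmarkSet(tuple(pos + neg), seed=seed, signal=signal, params=params)


def gc_contrast_benchmark(
    n_pos: int,
    n_neg: int,
    gc_pos: float = 0.40,
    gc_neg: float = 0.36,
    length_range: tuple[int, int] = (1800, 2400),
    seed: int = 0,
) -> BenchmarkSet:
    """Two frame-free base models differing only in GC fraction.

    The Bayes-optimal classifier is the exact base-composition likelihood
    ratio, so this benchmark has a computable error floor: the GC gap and
    length range set the separation.  The defaults give roughly 97% Bayes
    accuracy.
    """
    rng = np.random.default_rng(seed)
    seed_pos = int(rng.integers(0, 2**31 - 1))
    seed_neg = int(rng.integers(0, 2**31 - 1))
    pos_model = NoncodingModel(gc=gc_pos, length_range=length_range)
    neg_model = NoncodingModel(gc=gc_neg, length_range=length_range)
    pos = [
        LabeledSequence(s.seq_id.replace("noncod", "pos"), s.sequence, 1, "synthetic")
        for s in sample_noncoding(pos_model, n_pos, seed_pos)
    ]
    neg = sample_noncoding(neg_model, n_neg, seed_neg, id_prefix="neg")
    return BenchmarkSet(
        tuple(pos + neg),
        seed=seed,
        signal="gc_contrast",
        params={"gc_pos": gc_pos, "gc_neg": gc_neg, "length_range": length_range},
    )


def write_benchmark(benchmark: BenchmarkSet, fasta_path, label_path) -> None:
    """FASTA plus a tab-delimited (seq_id, label, source) companion table."""
    write_fasta(fasta_path, benchmark.sequences)
    write_label_table(label_path, benchmark.sequences)
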