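"""Frame-aware sequence-statistic encoders for ORF coding-potential assessment.

Six measurements, each a fixed-width block of frequencies computed on the
reading frame that starts at the first base of the sequence:

====  ==========================  =====
 id   measurement                 width
====  ==========================  =====
 1    mono-nucleotide by codon       12
      position (3 positions x 4)
 2    di-nucleotide on position      48
      pairs 1&2, 2&3 and 3&1
      (3 groups x 16)
 3    mono-codon usage               64
 4    di-codon usage               4096
 5    mono-amino-acid usage          21
      (stop counted as a 21st
      residue)
 6    di-amino-acid usage           441
====  ==========================  =====

The full concatenation is 4682-dimensional.  Within blocks the ordering is
frozen: nucleotide k-mers lexicographic over A < C < G < T, amino acids
alphabetical by one-letter code with the stop symbol ``*`` last.  Codons
containing characters outside {A, C, G, T} are excluded from every count and
every denominator; trailing bases beyond the last full codon are ignored.

Each normalisation group (one per codon position in block 1, one per pair
group in block 2, the whole block for 3-6) sums to exactly 1, or is all-zero
when it has no countable windows (e.g. the cross-codon groups of a
single-codon sequence).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "NUCLEOTIDES",
    "CODONS",
    "AA_ORDER",
    "GENETIC_CODE",
    "BLOCK_WIDTHS",
    "FULL_SELECTION",
    "TOTAL_WIDTH",
    "FEATURE_ORDER_VERSION",
    "FeatureBlock",
    "FeatureVector",
    "ScalingModel",
    "encode_mono_nt",
    "encode_di_nt",
    "encode_codon",
    "encode_dicodon",
    "encode_aa",
    "encode_diaa",
    "assemble",
    "encode_matrix",
    "feature_names",
    "fit_scaler",
    "apply_scaler",
    "first_position_gt",
    "write_feature_table",
    "read_feature_table",
    "write_svmlight",
    "read_svmlight",
]

NUCLEOTIDES = "ACGT"
CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)
)
#: Amino acids alphabetical by one-letter code, stop symbol last.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY*"

_standard_table = unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, with all three stop codons mapped to '*'.
GENETIC_CODE: dict[str, str] = {
    c: _standard_table.forward_table.get(c, "*") for c in CODONS
}

_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
_CODON_TO_AA = np.array([_AA_INDEX[GENETIC_CODE[c]] for c in CODONS], dtype=np.intp)

BLOCK_WIDTHS: dict[int, int] = {1: 12, 2: 48, 3: 64, 4: 4096, 5: 21, 6: 441}
FULL_SELECTION: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
TOTAL_WIDTH = sum(BLOCK_WIDTHS.values())  # 4682

#: Bump when the block/within-block ordering changes; persisted with models.
FEATURE_ORDER_VERSION = "orfsvm-features-1"

# byte -> base index, non-ACGT (incl. lowercase handled by upper() upstream) -> 4
_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(NUCLEOTIDES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class FeatureBlock:
    """One fixed-width block of frequencies for a single measurement."""

    measurement_id: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.measurement_id not in BLOCK_WIDTHS:
            raise ValueError(f"unknown measurement id {self.measurement_id}")
        expected = BLOCK_WIDTHS[self.measurement_id]
        if self.values.shape != (expected,):
            raise ValueError(
                f"measurement {self.measurement_id} expects width {expected}, "
                f"got {self.values.shape}"
            )

    @property
    def width(self) -> int:
        return BLOCK_WIDTHS[self.measurement_id]


@dataclass(frozen=True)
class FeatureVector:
    """Ordered concatenation of feature blocks (strictly increasing ids)."""

    blocks: tuple[FeatureBlock, ...]

    def __post_init__(self) -> None:
        ids = [b.measurement_id for b in self.blocks]
        if not ids:
            raise ValueError("feature vector needs at least one block")
        if ids != sorted(set(ids)):
            raise ValueError("blocks must have strictly increasing measurement ids")

    @property
    def selection(self) -> tuple[int, ...]:
        return tuple(b.measurement_id for b in self.blocks)

    @property
    def total_width(self) -> int:
        return sum(b.width for b in self.blocks)

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([b.values for b in self.blocks])


def _codon_array(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (m, 3) base-index array over full codons plus a validity mask.

    A codon is valid when all three bases are in {A, C, G, T}.  Raises on
    input shorter than one codon.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    m = len(seq) // 3
    arr = codes[: 3 * m].reshape(m, 3).astype(np.intp)
    valid = (arr < 4).all(axis=1)
    return arr, valid


def _normalize(counts: np.ndarray, denom: int) -> np.ndarray:
    if denom == 0:
        return np.zeros_like(counts, dtype=float)
    return counts / denom


def _mono_nt(seq: str) -> np.ndarray:
    arr, valid = _codon_array(seq)
    v = arr[valid]
    out = np.zeros(12)
    n = len(v)
    if n:
        for p in range(3):
            out[4 * p : 4 * p + 4] = np.bincount(v[:, p], minlength=4) / n
    return out


def _di_nt(seq: str) -> np.ndarray:
    arr, valid = _codon_array(seq)
    v = arr[valid]
    out = np.zeros(48)
    n = len(v)
    if n:
        out[0:16] = np.bincount(v[:, 0] * 4 + v[:, 1], minlength=16) / n
        out[16:32] = np.bincount(v[:, 1] * 4 + v[:, 2], minlength=16) / n
    # cross-codon group 3&1: pos3 of codon i with pos1 of codon i+1
    both = valid[:-1] & valid[1:]
    k = int(both.sum())
    if k:
        idx = arr[:-1, 2][both] * 4 + arr[1:, 0][both]
        out[32:48] = np.bincount(idx, minlength=16) / k
    return out


def _codon_indices(seq: str) -> tuple[np.ndarray, np.ndarray]:
    arr, valid = _codon_array(seq)
    idx = arr[:, 0] * 16 + arr[:, 1] * 4 + arr[:, 2]
    return idx, valid


def _mono_codon(seq: str) -> np.ndarray:
    idx, valid = _codon_indices(seq)
    n = int(valid.sum())
    return _normalize(np.bincount(idx[valid], minlength=64), n)


def _pair_mask(valid: np.ndarray, step: int) -> np.ndarray:
    """Mask over codon-pair windows (i, i+1); step 3 slides by one codon,
    step 6 takes disjoint pairs."""
    both = valid[:-1] & valid[1:]
    if step == 6:
        keep = np.zeros_like(both)
        keep[0::2] = True
        both = both & keep
    elif step != 3:
        raise ValueError("window step must be 3 or 6")
    return both


def _di_codon(seq: str, step: int = 3) -> np.ndarray:
    idx, valid = _codon_indices(seq)
    both = _pair_mask(valid, step)
    k = int(both.sum())
    if not k:
        return np.zeros(4096)
    pair = idx[:-1][both] * 64 + idx[1:][both]
    return np.bincount(pair, minlength=4096) / k


def _mono_aa(seq: str) -> np.ndarray:
    idx, valid = _codon_indices(seq)
    n = int(valid.sum())
    return _normalize(np.bincount(_CODON_TO_AA[idx[valid]], minlength=21), n)


def _di_aa(seq: str, step: int = 3) -> np.ndarray:
    idx, valid = _codon_indices(seq)
    aa = _CODON_TO_AA[np.where(valid, idx, 0)]
    both = _pair_mask(valid, step)
    k = int(both.sum())
    if not k:
        return np.zeros(441)
    pair = aa[:-1][both] * 21 + aa[1:][both]
    return np.bincount(pair, minlength=441) / k


def _encode_block(seq: str, measurement_id: int, step: int = 3) -> np.ndarray:
    seq = seq.upper()
    if measurement_id == 1:
        return _mono_nt(seq)
    if measurement_id == 2:
        return _di_nt(seq)
    if measurement_id == 3:
        return _mono_codon(seq)
    if measurement_id == 4:
        return _di_codon(seq, step)
    if measurement_id == 5:
        return _mono_aa(seq)
    if measurement_id == 6:
        return _di_aa(seq, step)
    raise ValueError(f"unknown measurement id {measurement_id}")


def encode_mono_nt(seq: str) -> FeatureBlock:
    """Base frequencies at codon positions 1-3 (position-major, A<C<G<T)."""
    return FeatureBlock(1, _encode_block(seq, 1))


def encode_di_nt(seq: str) -> FeatureBlock:
    """Dinucleotide frequencies on position pairs 1&2, 2&3 and cross-codon 3&1."""
    return FeatureBlock(2, _encode_block(seq, 2))


def encode_codon(seq: str) -> FeatureBlock:
    """Frequencies of the 64 codons over non-overlapping in-frame codons."""
    return FeatureBlock(3, _encode_block(seq, 3))


def encode_dicodon(seq: str, step: int = 3) -> FeatureBlock:
    """Frequencies of the 4096 codon pairs; windows advance by `step` bases."""
    return FeatureBlock(4, _encode_block(seq, 4, step))


def encode_aa(seq: str) -> FeatureBlock:
    """Frequencies of 20 amino acids plus stop (``*``) over in-frame codons."""
    return FeatureBlock(5, _encode_block(seq, 5))


def encode_diaa(seq: str, step: int = 3) -> FeatureBlock:
    """Frequencies of the 441 ordered residue pairs of consecutive codons."""
    return FeatureBlock(6, _encode_block(seq, 6, step))


def _check_selection(selection: Iterable[int]) -> tuple[int, ...]:
    sel = tuple(sorted(set(int(s) for s in selection)))
    if not sel:
        raise ValueError("feature selection must be non-empty")
    bad = [s for s in sel if s not in BLOCK_WIDTHS]
    if bad:
        raise ValueError(f"unknown measurement ids {bad}")
    return sel


def assemble(seq: str, selection: Iterable[int] = FULL_SELECTION, step: int = 3) -> FeatureVector:
    """Concatenate the selected blocks in measurement-id order."""
    sel = _check_selection(selection)
    return FeatureVector(
        tuple(FeatureBlock(s, _encode_block(seq, s, step)) for s in sel)
    )


def encode_matrix(
    seqs: Sequence[str], selection: Iterable[int] = FULL_SELECTION, step: int = 3
) -> np.ndarray:
    """Encode many sequences into a dense (n, width) matrix."""
    sel = _check_selection(selection)
    width = sum(BLOCK_WIDTHS[s] for s in sel)
    X = np.empty((len(seqs), width))
    for i, seq in enumerate(seqs):
        off = 0
        s_upper = seq.upper()
        for s in sel:
            w = BLOCK_WIDTHS[s]
            X[i, off : off + w] = _encode_block(s_upper, s, step)
            off += w
    return X


def feature_names(selection: Iterable[int] = FULL_SELECTION) -> list[str]:
    """Stable human-readable name per dimension, matching the frozen order."""
    sel = _check_selection(selection)
    names: list[str] = []
    for s in sel:
        if s == 1:
            names += [f"nt1_pos{p}_{b}" for p in (1, 2, 3) for b in NUCLEOTIDES]
        elif s == 2:
            dints = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=2)]
            for g in ("p12", "p23", "p31"):
                names += [f"dint_{g}_{d}" for d in dints]
        elif s == 3:
            names += [f"codon_{c}" for c in CODONS]
        elif s == 4:
            names += [f"dicodon_{a}{b}" for a in CODONS for b in CODONS]
        elif s == 5:
            names += [f"aa_{a}" for a in AA_ORDER]
        elif s == 6:
            names += [f"diaa_{a}{b}" for a in AA_ORDER for b in AA_ORDER]
    return names


@dataclass
class ScalingModel:
    """Per-dimension min/max learned on training vectors, applied unchanged.

    Transform is (x - min) / (max - min); constant dimensions map to 0.
    Test values outside the training range are not clipped and may fall
    outside [0, 1].
    """

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if self.mins.shape != self.maxs.shape or self.mins.ndim != 1:
            raise ValueError("mins and maxs must be 1-D arrays of equal length")
        if np.any(self.maxs < self.mins):
            raise ValueError("per-dimension max must be >= min")

    @property
    def width(self) -> int:
        return self.mins.shape[0]

    @classmethod
    def fit(cls, X: np.ndarray) -> "ScalingModel":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < 1:
            raise ValueError("need at least one vector to fit the scaler")
        return cls(mins=X.min(axis=0), maxs=X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.width:
            raise ValueError(
                f"width mismatch: scaler has {self.width}, data has {X.shape[-1]}"
            )
        span = self.maxs - self.mins
        out = X - self.mins
        constant = span == 0
        # constant training dimensions carry no information: map to 0
        out[..., constant] = 0.0
        out[..., ~constant] = out[..., ~constant] / span[~constant]
        return out


def fit_scaler(X: np.ndarray) -> ScalingModel:
    """Learn per-dimension min/max on training vectors."""
    return ScalingModel.fit(X)


def apply_scaler(model: ScalingModel, X: np.ndarray) -> np.ndarray:
    """Apply a stored training scale to new vectors (unclipped)."""
    return model.transform(X)


def first_position_gt(seq: str) -> tuple[float, float]:
    """(G, T) frequencies at the first codon position.

    Coding sequences tend toward guanine and away from thymine at codon
    position 1, making this 2-D projection a quick coding-vs-spurious
    diagnostic.
    """
    block = _encode_block(seq, 1)
    return float(block[2]), float(block[3])


# ---------------------------------------------------------------------------
# feature-matrix serialization


def write_feature_table(path, X, selection=FULL_SELECTION, ids=None) -> None:
    """Dense tab-delimited matrix with a header naming every dimension."""
    import pandas as pd

    names = feature_names(selection)
    df = pd.DataFrame(np.atleast_2d(X), columns=names)
    if ids is not None:
        df.insert(0, "seq_id", list(ids))
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path):
    """Read a matrix written by :func:`write_feature_table`.

    Returns (X, ids) where ids is None when the table has no seq_id column.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    ids = None
    if "seq_id" in df.columns:
        ids = df["seq_id"].tolist()
        df = df.drop(columns="seq_id")
    return df.to_numpy(dtype=float), ids


def write_svmlight(path, X, y) -> None:
    """Sparse ``label index:value`` classifier-exchange format (1-based)."""
    from sklearn.datasets import dump_svmlight_file

    dump_svmlight_file(np.atleast_2d(X), np.asarray(y), str(path), zero_based=False)


def read_svmlight(path, n_features=None):
    from sklearn.datasets import load_svmlight_file

    X, y = load_svmlight_file(str(path), n_features=n_features, zero_based=False)
    return X.toarray(), y.astype(int)
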