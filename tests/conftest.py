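import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests._oracles as _oracles

from orfsvm.annotation_io import GenomeSequence, OrfRecord
from orfsvm.synthetic import (
    CodingModel,
    NoncodingModel,
    make_benchmark,
    sample_coding,
    sample_noncoding,
    tilted_codon_table,
)

from _oracles import reverse_complement


@pytest.fixture(scope="session")
def strong_small():
    """Small near-separable benchmark for fast classifier tests."""
    return make_benchmark(120, 120, signal="strong", seed=11)


@pytest.fixture(scope="session")
def planted_locus():
    """A synthetic chromosome with planted coding/noncoding ORFs.

    Returns (genomes, records, meta) where meta records which test ORFs were
    planted from the coding model and which from the background model.
    """
    rng = np.random.default_rng(202)
    coding_model = CodingModel(
        codon_probs=tilted_codon_table(gc=0.5, tilt=2.0, lead_g_bonus=1.0),
        length_range=(80, 160),
    )
    background = NoncodingModel(gc=0.5, length_range=(350, 500))

    verified = sample_coding(coding_model, 30, seed=1, id_prefix="VER")
    test_coding = sample_coding(coding_model, 10, seed=2, id_prefix="TCOD")
    test_noncoding = sample_noncoding(background, 5, seed=3, id_prefix="TNON")
    # trim planted noncoding test ORFs to codon multiples >= 3 (they are ORF
    # records, not intergenic runs)
    test_noncoding = [
        type(s)(s.seq_id, s.sequence[: len(s.sequence) // 3 * 3], s.label, s.source)
        for s in test_noncoding
    ]
    spacers = sample_noncoding(background, 60, seed=4, id_prefix="SPACE")

    pieces = []
    records = []
    cursor = 1
    spacer_iter = iter(spacers)
    orfs = (
        [("verified", s) for s in verified]
        + [("uncharacterized", s) for s in test_coding]
        + [("dubious", s) for s in test_noncoding]
    )
    order = rng.permutation(len(orfs))
    for j, idx in enumerate(order):
        category, labeled = orfs[idx]
        spacer = next(spacer_iter).sequence
        pieces.append(spacer)
        cursor += len(spacer)
        strand = "+" if j % 3 else "-"
        seq = labeled.sequence if strand == "+" else reverse_complement(labeled.sequence)
        pieces.append(seq)
        records.append(
            OrfRecord(
                orf_id=labeled.seq_id,
                chrom_id="chrS",
                start=cursor,
                end=cursor + len(seq) - 1,
                strand=strand,
                category=category,
            )
        )
        cursor += len(seq)
    pieces.append(next(spacer_iter).sequence)
    genome = GenomeSequence("chrS", "".join(pieces))
    meta = {
        "coding_test_ids": [s.seq_id for s in test_coding],
        "noncoding_test_ids": [s.seq_id for s in test_noncoding],
        "verified_ids": [s.seq_id for s in verified],
    }
    return [genome], records, meta
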