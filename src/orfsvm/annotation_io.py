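"""Genome/annotation reading, ORF and intergenic extraction, overlap analysis.

Coordinate convention: external files are 1-based inclusive (GFF style);
conversion to Python's 0-based half-open slices happens only at the point of
sequence extraction.  Minus-strand ORF sequences are reported 5'->3' on the
coding strand (reverse complement), since every downstream feature is frame-
and strand-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "GenomeSequence",
    "OrfRecord",
    "LabeledSequence",
    "OverlapPair",
    "OverlapReport",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "extract_orf_sequence",
    "extract_intergenic",
    "build_datasets",
    "classify_overlaps",
    "read_label_table",
    "write_label_table",
]

#: The three evidence categories an annotated ORF may carry.
CATEGORIES = ("verified", "uncharacterized", "dubious")


@dataclass(frozen=True)
class GenomeSequence:
    """A chromosome or contig; sequence uppercase over IUPAC codes."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.chrom_id:
            raise ValueError("empty chromosome id")
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.chrom_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfRecord:
    """An annotated ORF with 1-based inclusive coordinates."""

    orf_id: str
    chrom_id: str
    start: int
    end: int
    strand: str
    category: str
    gene_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.orf_id}: start {self.start} > end {self.end}"
            )
        if self.end - self.start + 1 < 3:
            raise ValueError(f"{self.orf_id}: shorter than one codon")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.orf_id}: strand must be + or -")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.orf_id}: unknown category {self.category!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class LabeledSequence:
    """A sequence with a class label: +1 coding, -1 noncoding, 0 unresolved."""

    seq_id: str
    sequence: str
    label: int
    source: str = "synthetic"


@dataclass(frozen=True)
class OverlapPair:
    candidate_id: str
    partner_id: Optional[str]
    overlap_bp: int
    orientation: Optional[str]  # same_strand | antisense | None


@dataclass(frozen=True)
class OverlapReport:
    pairs: tuple[OverlapPair, ...]
    n_candidates: int
    n_overlapping: int
    n_antisense: int

    @property
    def antisense_fraction(self) -> float:
        if self.n_overlapping == 0:
            return 0.0
        return self.n_antisense / self.n_overlapping


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[GenomeSequence]:
    """Read a (possibly line-wrapped) multi-record FASTA, uppercasing."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: FASTA record with empty header")
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: empty record {rec.id!r}")
        out.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(path, records: Iterable) -> None:
    """Write GenomeSequence or LabeledSequence records as FASTA."""
    seqrecs = []
    for r in records:
        rid = getattr(r, "chrom_id", None) or getattr(r, "seq_id")
        seqrecs.append(SeqRecord(Seq(r.sequence), id=rid, description=""))
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# annotations


def _normalize_category(raw: str) -> Optional[str]:
    cat = raw.strip().lower()
    return cat if cat in CATEGORIES else None


def _read_gff3(path) -> list[OrfRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[OrfRecord] = []
    skipped = 0
    for feat in db.all_features():
        attrs = {k.lower(): v for k, v in feat.attributes.items()}
        raw_cat = attrs.get("orf_classification") or attrs.get("category")
        if not raw_cat:
            continue  # not an ORF row (chromosome, ARS, tRNA, ...)
        category = _normalize_category(raw_cat[0])
        if category is None:
            skipped += 1
            logger.warning(
                "%s: skipping %s with unknown category %r", path, feat.id, raw_cat[0]
            )
            continue
        if feat.start > feat.end:
            raise ValueError(f"{path}: {feat.id} start > end")
        gene = attrs.get("gene", [None])[0]
        records.append(
            OrfRecord(
                orf_id=feat.id,
                chrom_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                category=category,
                gene_name=gene,
            )
        )
    if skipped:
        logger.warning("%s: skipped %d rows with unknown categories", path, skipped)
    return records


_TAB_COLUMNS = ["orf_id", "gene_name", "chrom_id", "start", "end", "strand", "category"]


def _read_sgd_tab(path) -> list[OrfRecord]:
    import pandas as pd

    df = pd.read_csv(
        path, sep="\t", header=None, names=_TAB_COLUMNS, comment="#", dtype=str
    )
    records: list[OrfRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        category = _normalize_category(row.category or "")
        if category is None:
            skipped += 1
            logger.warning(
                "%s: skipping %s with unknown category %r", path, row.orf_id, row.category
            )
            continue
        start, end = int(row.start), int(row.end)
        if start > end:
            raise ValueError(f"{path}: {row.orf_id} start > end")
        gene = None if pd.isna(row.gene_name) or row.gene_name in ("", "-") else row.gene_name
        records.append(
            OrfRecord(row.orf_id, row.chrom_id, start, end, row.strand, category, gene)
        )
    if skipped:
        logger.warning("%s: skipped %d rows with unknown categories", path, skipped)
    return records


def read_annotation(path, dialect: str = "gff3") -> list[OrfRecord]:
    """Read ORF records from a GFF3 file or an SGD-style tab table.

    The tab dialect has columns (systematic name, gene name, chromosome,
    start, end, strand, category).  Rows whose category is not one of
    verified/uncharacterized/dubious are skipped with a logged warning.
    """
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "sgd_tab":
        return _read_sgd_tab(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


# ---------------------------------------------------------------------------
# sequence extraction

_CATEGORY_SOURCE = {
    "verified": "verified_orf",
    "uncharacterized": "uncharacterized",
    "dubious": "dubious",
}
_CATEGORY_LABEL = {"verified": 1, "uncharacterized": 0, "dubious": 0}


def extract_orf_sequence(genome: GenomeSequence, orf: OrfRecord) -> LabeledSequence:
    """Strand-aware ORF sequence: minus-strand ORFs are reverse-complemented.

    Verified ORFs carry the coding label +1; uncharacterized and dubious
    ORFs are the unresolved test material and carry label 0.
    """
    if orf.start < 1 or orf.end > len(genome):
        raise ValueError(
            f"{orf.orf_id}: [{orf.start}, {orf.end}] outside {genome.chrom_id} "
            f"(length {len(genome)})"
        )
    sub = genome.sequence[orf.start - 1 : orf.end]
    if orf.strand == "-":
        sub = str(Seq(sub).reverse_complement())
    return LabeledSequence(
        seq_id=orf.orf_id,
        sequence=sub,
        label=_CATEGORY_LABEL[orf.category],
        source=_CATEGORY_SOURCE[orf.category],
    )


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals, sorted."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def extract_intergenic(
    genome: GenomeSequence,
    records: Sequence[OrfRecord],
    min_len: int = 300,
) -> list[LabeledSequence]:
    """Maximal genome runs covered by no annotated ORF on either strand.

    Both strands collapse onto one coordinate track; only runs strictly
    longer than `min_len` are kept (default 300 bp), labeled noncoding.
    """
    covered = _merge_intervals(
        [(r.start, r.end) for r in records if r.chrom_id == genome.chrom_id]
    )
    gaps: list[tuple[int, int]] = []
    cursor = 1
    for s, e in covered:
        if s > cursor:
            gaps.append((cursor, s - 1))
        cursor = max(cursor, e + 1)
    if cursor <= len(genome):
        gaps.append((cursor, len(genome)))
    out = []
    for s, e in gaps:
        if e - s + 1 > min_len:
            out.append(
                LabeledSequence(
                    seq_id=f"{genome.chrom_id}_ig_{s}_{e}",
                    sequence=genome.sequence[s - 1 : e],
                    label=-1,
                    source="intergenic",
                )
            )
    return out


def build_datasets(
    genomes: Sequence[GenomeSequence],
    records: Sequence[OrfRecord],
    min_intergenic_len: int = 300,
) -> dict[str, list[LabeledSequence]]:
    """Training/test sets from a genome and its annotation.

    positives: verified ORFs (label +1); negatives: intergenic runs longer
    than the threshold (label -1); test: uncharacterized + dubious ORFs
    (label 0).  Intergenic extraction removes the union of ALL annotated
    ORFs, whatever their category, on both strands.
    """
    by_chrom = {g.chrom_id: g for g in genomes}
    positives: list[LabeledSequence] = []
    test: list[LabeledSequence] = []
    negatives: list[LabeledSequence] = []
    for orf in records:
        genome = by_chrom.get(orf.chrom_id)
        if genome is None:
            raise ValueError(f"{orf.orf_id}: no genome sequence for {orf.chrom_id}")
        seq = extract_orf_sequence(genome, orf)
        if orf.category == "verified":
            if len(seq.sequence) % 3 != 0:
                logger.warning(
                    "verified ORF %s has length %d not divisible by 3",
                    orf.orf_id,
                    len(seq.sequence),
                )
            positives.append(seq)
        else:
            test.append(seq)
    for genome in genomes:
        negatives.extend(extract_intergenic(genome, records, min_intergenic_len))
    return {"positives": positives, "negatives": negatives, "test": test}


# ---------------------------------------------------------------------------
# overlaps


def _overlap_bp(a: OrfRecord, b: OrfRecord) -> int:
    if a.chrom_id != b.chrom_id:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def classify_overlaps(
    candidates: Sequence[OrfRecord], reference: Sequence[OrfRecord]
) -> OverlapReport:
    """For each candidate, the reference ORF it overlaps most (>= 1 bp).

    Orientation is antisense when the strands differ.  The summary reports
    the overlapping count and the antisense fraction among overlapping
    candidates — a diagnostic for spurious annotations, which tend to sit on
    the antisense strand of real genes.
    """
    by_chrom: dict[str, list[OrfRecord]] = {}
    for r in reference:
        by_chrom.setdefault(r.chrom_id, []).append(r)
    pairs: list[OverlapPair] = []
    n_overlapping = 0
    n_antisense = 0
    for cand in candidates:
        best: Optional[OrfRecord] = None
        best_bp = 0
        for ref in by_chrom.get(cand.chrom_id, ()):
            if ref.orf_id == cand.orf_id:
                continue
            bp = _overlap_bp(cand, ref)
            if bp > best_bp or (bp == best_bp and bp > 0 and ref.start < best.start):
                best, best_bp = ref, bp
        if best is None or best_bp == 0:
            pairs.append(OverlapPair(cand.orf_id, None, 0, None))
        else:
            orientation = "same_strand" if cand.strand == best.strand else "antisense"
            n_overlapping += 1
            if orientation == "antisense":
                n_antisense += 1
            pairs.append(OverlapPair(cand.orf_id, best.orf_id, best_bp, orientation))
    return OverlapReport(tuple(pairs), len(candidates), n_overlapping, n_antisense)


# ---------------------------------------------------------------------------
# label tables (FASTA companion emitted by the synthetic generator)


def write_label_table(path, sequences: Iterable[LabeledSequence]) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tlabel\tsource\n")
        for s in sequences:
            fh.write(f"{s.seq_id}\t{s.label}\t{s.source}\n")


def read_label_table(path) -> dict[str, tuple[int, str]]:
    out: dict[str, tuple[int, str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("seq_id"):
            raise ValueError(f"{path}: missing label-table header")
        for line in fh:
            seq_id, label, source = line.rstrip("\n").split("\t")
            out[seq_id] = (int(label), source)
    return out
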