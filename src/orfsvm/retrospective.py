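"""Snapshot-comparison validation: does a model trained on an older
annotation already recognise the genes that were verified later?

For each adjacent pair of annotation snapshots:

1. build training sets (verified ORFs + long intergenic runs) from the
   older snapshot;
2. train the class-weighted linear SVM;
3. predict the older snapshot's unresolved (uncharacterized + dubious) ORFs;
4. find ORFs annotated in *both* snapshots that moved from a non-verified
   category to verified in the newer one;
5. report the coverage ratio: the percentage of those newly verified genes
   the model had already called coding.

High coverage across a snapshot series is collateral evidence that the
classifier's calls on still-unresolved ORFs are trustworthy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .annotation_io import GenomeSequence, OrfRecord, build_datasets
from .classifier import predict_orfs, train_on_sequences
from .config import RunConfig

__all__ = [
    "Snapshot",
    "CoverageResult",
    "newly_verified",
    "snapshot_coverage",
    "run_series",
    "coverage_from_counts",
    "pooled_coverage",
]


@dataclass(frozen=True)
class Snapshot:
    """One dated annotation state: a label plus its ORF records."""

    label: str
    records: tuple[OrfRecord, ...]
    genome_label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.orf_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"snapshot {self.label}: duplicate orf_ids {dupes[:5]}")

    def by_id(self) -> dict[str, OrfRecord]:
        return {r.orf_id: r for r in self.records}


@dataclass(frozen=True)
class CoverageResult:
    older_label: str
    newer_label: str
    n_new_verified: int
    n_predicted: int  # predicted-coding among ALL of the older test ORFs
    missed: tuple[str, ...]  # newly verified genes the model did not call coding

    @property
    def coverage(self) -> Optional[float]:
        """Percent of newly verified genes predicted coding; None if no new genes."""
        if self.n_new_verified == 0:
            return None
        return coverage_from_counts(self.n_new_verified, len(self.missed))


def coverage_from_counts(n_new: int, n_missed: int) -> float:
    """Coverage percentage from the newly-verified count and the missed count."""
    if n_new <= 0:
        raise ValueError("coverage undefined without newly verified genes")
    if not 0 <= n_missed <= n_new:
        raise ValueError("missed count must be between 0 and the new-gene count")
    return 100.0 * (n_new - n_missed) / n_new


def pooled_coverage(pairs: Sequence[tuple[int, int]]) -> float:
    """Pooled coverage over a series: 100 * sum(hits) / sum(new).

    Each pair is (n_new_verified, n_missed) for one adjacent-snapshot
    comparison.
    """
    total_new = sum(n for n, _ in pairs)
    total_missed = sum(m for _, m in pairs)
    return coverage_from_counts(total_new, total_missed)


def newly_verified(older: Snapshot, newer: Snapshot) -> set[str]:
    """ORFs annotated in both snapshots whose category became verified.

    Matching is by systematic name; ORFs present only in the newer snapshot
    are excluded, as are ORFs already verified in the older one.
    """
    older_by_id = older.by_id()
    out = set()
    for rec in newer.records:
        old = older_by_id.get(rec.orf_id)
        if old is not None and old.category != "verified" and rec.category == "verified":
            out.add(rec.orf_id)
    return out


def snapshot_coverage(
    genomes: Sequence[GenomeSequence],
    older: Snapshot,
    newer: Snapshot,
    config: RunConfig = RunConfig(),
) -> CoverageResult:
    """Train on the older snapshot, measure coverage of the newer one's
    newly verified genes."""
    datasets = build_datasets(genomes, older.records, config.min_intergenic_len)
    positives, negatives, test = (
        datasets["positives"],
        datasets["negatives"],
        datasets["test"],
    )
    if not positives or not negatives:
        raise ValueError(
            f"snapshot {older.label}: need verified ORFs and intergenic runs to train"
        )
    sequences = [s.sequence for s in positives + negatives]
    labels = [1] * len(positives) + [-1] * len(negatives)
    model = train_on_sequences(
        sequences,
        labels,
        selection=config.selection,
        C=config.C,
        w_ratio=config.w_ratio,
        step=config.dicodon_step,
        random_state=config.seed,
    )
    predictions = predict_orfs(model, [(s.seq_id, s.sequence) for s in test])
    predicted_coding = {p.seq_id for p in predictions if p.label == "coding"}
    new = newly_verified(older, newer)
    missed = tuple(sorted(new - predicted_coding))
    return CoverageResult(
        older_label=older.label,
        newer_label=newer.label,
        n_new_verified=len(new),
        n_predicted=len(predicted_coding),
        missed=missed,
    )


def run_series(
    genomes: Sequence[GenomeSequence],
    snapshots: Sequence[Snapshot],
    config: RunConfig = RunConfig(),
) -> tuple[list[CoverageResult], Optional[float]]:
    """Pairwise adjacent comparison over an ordered snapshot series.

    Returns the per-pair results and the pooled coverage (None when no pair
    contributed newly verified genes).
    """
    if len(snapshots) < 2:
        raise ValueError("a snapshot series needs at least two snapshots")
    results = [
        snapshot_coverage(genomes, older, newer, config)
        for older, newer in zip(snapshots[:-1], snapshots[1:])
    ]
    contributing = [(r.n_new_verified, len(r.missed)) for r in results if r.n_new_verified]
    pooled = pooled_coverage(contributing) if contributing else None
    return results, pooled
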