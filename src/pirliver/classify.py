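"""Read collapsing and sncRNA class assignment.

Collapses trimmed FASTQ reads to unique sequences with per-sample counts,
then assigns each sequence to a known sncRNA class (piRNA, miRNA, rRNA,
tRNA, snoRNA) by exact match against an annotation index, or to the
unannotated pool.  Ambiguous sequences are resolved by a configurable class
priority: non-piRNA classes absorb shared sequences first, so only reads
that match nothing else can count as piRNAs.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import io

logger = logging.getLogger(__name__)

DEFAULT_PRIORITY = ("miRNA", "rRNA", "tRNA", "snoRNA", "piRNA")
UNANNOTATED = "unannotated"
DEFAULT_WINDOW = (18, 40)

DISCARD_COLUMNS = ["too_short", "too_long", "with_n", "kept"]


class AnnotationIndex:
    """Exact-match lookup from sequence to (class, identifier).

    Built from (id, class, sequence) records; duplicate sequences within a
    class are rejected at load.  ``priority`` fixes the order in which classes
    claim a sequence that occurs in more than one class.
    """

    def __init__(self, records: Iterable[tuple[str, str, str]],
                 priority: Sequence[str] = DEFAULT_PRIORITY):
        self._by_class: dict[str, dict[str, str]] = {}
        for ident, cls, seq in records:
            seq = seq.upper()
            table = self._by_class.setdefault(cls, {})
            if seq in table and table[seq] != ident:
                raise ValueError(
                    f"duplicate sequence within class {cls!r}: {table[seq]} vs {ident}"
                )
            table[seq] = ident
        extra = sorted(set(self._by_class) - set(priority))
        self.priority: tuple[str, ...] = tuple(
            [c for c in priority if c in self._by_class] + extra
        )

    @classmethod
    def from_fasta(cls, path: str | Path,
                   priority: Sequence[str] = DEFAULT_PRIORITY) -> "AnnotationIndex":
        """Load from a FASTA with ``>ID|CLASS`` headers."""
        records = []
        for header, seq in io.read_fasta(path).items():
            if "|" not in header:
                raise ValueError(f"annotation header {header!r} lacks '|CLASS' suffix")
            ident, cls_name = header.rsplit("|", 1)
            records.append((ident, cls_name, seq))
        return cls(records, priority)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   priority: Sequence[str] = DEFAULT_PRIORITY) -> "AnnotationIndex":
        """Load from a frame with columns id, rna_class, sequence."""
        return cls(
            [(r.id, r.rna_class, r.sequence) for r in df.itertuples(index=False)],
            priority,
        )

    def lookup(self, seq: str) -> tuple[str, str]:
        for cls_name in self.priority:
            ident = self._by_class[cls_name].get(seq)
            if ident is not None:
                return cls_name, ident
        return UNANNOTATED, ""

    def sequences(self, cls_name: str) -> dict[str, str]:
        return dict(self._by_class.get(cls_name, {}))


def collapse_fastq(
    sample_fastqs: Mapping[str, str | Path],
    length_window: tuple[int, int] = DEFAULT_WINDOW,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse per-sample FASTQs to a unique-sequence x sample count table.

    Reads outside the length window or containing N are excluded and tallied
    in the per-sample discard report.  Count conservation: per sample,
    column sum + discards = input records.
    """
    lo, hi = length_window
    counters: dict[str, dict[str, int]] = {}
    discard_rows = {}
    for sample, path in sample_fastqs.items():
        counter: dict[str, int] = {}
        d = {c: 0 for c in DISCARD_COLUMNS}
        for _rid, seq in io.iter_fastq(path):
            if "N" in seq:
                d["with_n"] += 1
            elif len(seq) < lo:
                d["too_short"] += 1
            elif len(seq) > hi:
                d["too_long"] += 1
            else:
                counter[seq] = counter.get(seq, 0) + 1
                d["kept"] += 1
        counters[sample] = counter
        discard_rows[sample] = d
    counts = pd.DataFrame(counters).fillna(0).astype(int)
    counts = counts.sort_index()
    counts.index.name = "sequence"
    counts.columns.name = None
    discards = pd.DataFrame.from_dict(discard_rows, orient="index")[DISCARD_COLUMNS]
    discards.index.name = "sample"
    return counts, discards


def assign_classes(counts: pd.DataFrame, index: AnnotationIndex) -> pd.DataFrame:
    """Annotate each collapsed sequence with (assigned_class, assigned_id)."""
    pairs = [index.lookup(seq) for seq in counts.index]
    out = counts.copy()
    out["assigned_class"] = [p[0] for p in pairs]
    out["assigned_id"] = [p[1] for p in pairs]
    return out


def _sample_columns(assigned: pd.DataFrame) -> list[str]:
    return [c for c in assigned.columns if c not in ("assigned_class", "assigned_id")]


def pirna_count_matrix(assigned: pd.DataFrame, rna_class: str = "piRNA") -> pd.DataFrame:
    """Per-piRNA raw counts; sequence variants sharing one ID are summed.

    Rows with zero total count are dropped (a piRNA is 'detected' only if it
    was sequenced somewhere).
    """
    samples = _sample_columns(assigned)
    sub = assigned[assigned["assigned_class"] == rna_class]
    if sub.empty:
        logger.warning("no sequences assigned to class %r", rna_class)
        mat = pd.DataFrame(columns=samples)
        mat.index.name = "feature_id"
        return mat
    mat = sub.groupby("assigned_id")[samples].sum()
    mat = mat[mat.sum(axis=1) > 0].sort_index()
    mat.index.name = "feature_id"
    return mat


def detection_report(matrix: pd.DataFrame, meta: pd.DataFrame) -> tuple[pd.Series, dict[str, set[str]]]:
    """Distinct features detected per stage group, and per-feature stage sets."""
    stage_of = dict(zip(meta["sample"], meta["stage"]))
    per_feature: dict[str, set[str]] = {}
    for fid, row in matrix.iterrows():
        per_feature[fid] = {stage_of[s] for s in matrix.columns if row[s] > 0}
    stages = sorted(set(stage_of.values()))
    counts = pd.Series(
        {st: sum(1 for groups in per_feature.values() if st in groups) for st in stages},
        name="n_detected",
    )
    counts.index.name = "stage"
    return counts, per_feature


def unannotated_pool(assigned: pd.DataFrame) -> pd.DataFrame:
    """Count table of sequences that matched no annotation class."""
    samples = _sample_columns(assigned)
    return assigned.loc[assigned["assigned_class"] == UNANNOTATED, samples].copy()


def class_totals(assigned: pd.DataFrame) -> pd.DataFrame:
    """Per-sample read totals by assigned class (conservation accounting)."""
    samples = _sample_columns(assigned)
    return assigned.groupby("assigned_class")[samples].sum()
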