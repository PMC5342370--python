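"""Novel piRNA-like discovery: scoring, genome placement, locus building.

Unannotated piRNA-sized sequences (25-35 nt by default) are scored with a
transparent k-mer (1..5-mer) logistic discriminant trained on the known
piRNA set against decoy/shuffled sequences; retained candidates are placed
in the genome by exact matching on both strands (capped multi-mapping), and
strand-aware loci ("piR_LLi_N") are built by interval merging with summed
per-sample coverage.
"""
from __future__ import annotations

from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .util import revcomp

DEFAULT_DISCOVERY_WINDOW = (25, 35)
DEFAULT_MAX_PLACEMENTS = 30  # a single somatic piRNA was seen at up to 28 loci


def _kmer_vocabulary(k_min: int, k_max: int) -> dict[str, int]:
    vocab = {}
    for k in range(k_min, k_max + 1):
        for kmer in product("ACGT", repeat=k):
            vocab["".join(kmer)] = len(vocab)
    return vocab


def kmer_features(sequences: Sequence[str], k_min: int = 1, k_max: int = 5,
                  vocab: dict[str, int] | None = None) -> np.ndarray:
    """Per-k length-normalized k-mer frequency vectors."""
    if vocab is None:
        vocab = _kmer_vocabulary(k_min, k_max)
    X = np.zeros((len(sequences), len(vocab)), dtype=np.float64)
    for i, seq in enumerate(sequences):
        L = len(seq)
        for k in range(k_min, k_max + 1):
            n_windows = L - k + 1
            if n_windows <= 0:
                continue
            w = 1.0 / n_windows
            row = X[i]
            for j in range(n_windows):
                idx = vocab.get(seq[j : j + k])
                if idx is not None:
                    row[idx] += w
    return X


class KmerDiscriminant(BaseEstimator):
    """Logistic k-mer-frequency discriminant for piRNA-likeness.

    sklearn-style estimator: ``fit(sequences, y)`` with y=1 for piRNA-like
    positives, then ``score_sequences`` returns P(piRNA-like) in [0, 1].
    Deterministic given ``random_state``.
    """

    def __init__(self, k_min: int = 1, k_max: int = 5, C: float = 1.0,
                 min_training: int = 20, random_state: int = 0):
        self.k_min = k_min
        self.k_max = k_max
        self.C = C
        self.min_training = min_training
        self.random_state = random_state

    def fit(self, sequences: Sequence[str], y: Sequence[int]) -> "KmerDiscriminant":
        y = np.asarray(y, dtype=int)
        if len(sequences) != len(y):
            raise ValueError("sequences and labels differ in length")
        n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
        if min(n_pos, n_neg) < self.min_training:
            raise ValueError(
                f"training set too small: {n_pos} positives / {n_neg} negatives "
                f"(minimum {self.min_training} each)"
            )
        self.vocab_ = _kmer_vocabulary(self.k_min, self.k_max)
        X = kmer_features(sequences, self.k_min, self.k_max, self.vocab_)
        # balanced weights keep P=0.5 a usable retention threshold when the
        # positive and negative training sets differ in size
        self.model_ = LogisticRegression(
            C=self.C, max_iter=2000, class_weight="balanced",
            random_state=self.random_state,
        ).fit(X, y)
        return self

    def score_sequences(self, sequences: Sequence[str]) -> np.ndarray:
        X = kmer_features(sequences, self.k_min, self.k_max, self.vocab_)
        return self.model_.predict_proba(X)[:, 1]

    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        return (self.score_sequences(sequences) >= 0.5).astype(int)


def _shuffle_seq(rng: np.random.Generator, seq: str) -> str:
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


def score_pirna_like(
    pool: pd.DataFrame,
    positives: Sequence[str],
    negatives: Sequence[str] | None = None,
    seed: int = 0,
    threshold: float = 0.5,
    length_window: tuple[int, int] = DEFAULT_DISCOVERY_WINDOW,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Score unannotated sequences and retain piRNA-like candidates.

    ``pool`` is a sequence x sample count table.  The discriminant trains on
    the known-piRNA positives against the supplied negatives plus per-positive
    mononucleotide shuffles (which erase the learnable k-mer structure).
    Sequences outside the discovery length window are dropped first; retained
    candidates carry a ``score`` column.
    """
    rng = np.random.default_rng([seed, 67])
    lo, hi = length_window
    lengths = pool.index.str.len()
    windowed = pool[(lengths >= lo) & (lengths <= hi)]

    neg = list(negatives) if negatives else []
    neg += [_shuffle_seq(rng, s) for s in positives]
    train = list(positives) + neg
    labels = [1] * len(positives) + [0] * len(neg)
    disc = KmerDiscriminant(random_state=seed).fit(train, labels)

    if len(windowed):
        scores = disc.score_sequences(list(windowed.index))
    else:
        scores = np.array([])
    candidates = windowed.copy()
    candidates["score"] = scores
    retained = candidates[candidates["score"] >= threshold]
    report = {
        "n_pool": int(len(pool)),
        "n_outside_window": int(len(pool) - len(windowed)),
        "n_low_score": int(len(windowed) - len(retained)),
        "n_retained": int(len(retained)),
    }
    return retained, report


def _scan(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def map_candidates(
    candidates: pd.DataFrame,
    genome: Mapping[str, str],
    max_placements: int = DEFAULT_MAX_PLACEMENTS,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """All exact-match genomic placements of each candidate, both strands.

    Candidates with zero placements or with more than ``max_placements``
    placements are dropped and returned in the unmapped / repetitive reports.
    A candidate equal to its own reverse complement yields placements on both
    strands of the same interval.
    """
    rows = []
    unmapped: list[str] = []
    repetitive: list[str] = []
    contigs = sorted(genome)
    for seq in candidates.index:
        L = len(seq)
        rc = revcomp(seq)
        placements = set()
        for contig in contigs:
            cseq = genome[contig]
            for i in _scan(cseq, seq):
                placements.add((contig, i, i + L, "+"))
            for i in _scan(cseq, rc):
                placements.add((contig, i, i + L, "-"))
        if not placements:
            unmapped.append(seq)
        elif len(placements) > max_placements:
            repetitive.append(seq)
        else:
            for contig, s, e, strand in sorted(placements):
                rows.append(
                    {"sequence": seq, "contig": contig, "start": s, "end": e, "strand": strand}
                )
    alignments = pd.DataFrame(rows, columns=["sequence", "contig", "start", "end", "strand"])
    if len(alignments):
        alignments = alignments.sort_values(
            ["contig", "start", "end", "strand", "sequence"], ignore_index=True
        )
    return alignments, unmapped, repetitive


def merge_intervals(intervals: Sequence[tuple[int, int]], merge_distance: int = 0
                    ) -> list[tuple[int, int]]:
    """Union of intervals, merging pairs that overlap or whose gap is at most
    ``merge_distance``.  Idempotent."""
    if merge_distance < 0:
        raise ValueError("merge_distance must be >= 0")
    if not intervals:
        return []
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + merge_distance:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_loci(
    alignments: pd.DataFrame,
    pool_counts: pd.DataFrame,
    merge_distance: int = 0,
    min_reads: int = 1,
    mito_contigs: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge strand-aware alignments into piR_LLi loci with coverage.

    Alignments on the same contig and strand whose intervals overlap or lie
    within ``merge_distance`` form one locus.  Each member sequence
    contributes its full per-sample count to every locus it maps in
    (multi-origin sequences are not split); the per-locus multimap fraction
    reports the coverage share from multi-placed sequences.  Loci are
    numbered piR_LLi_1.. in (contig, start, strand) order.

    Returns (locus table, locus x sample coverage matrix).
    """
    if merge_distance < 0:
        raise ValueError("merge_distance must be >= 0")
    samples = [c for c in pool_counts.columns if c != "score"]
    placements_per_seq = (
        alignments.groupby("sequence").size() if len(alignments) else pd.Series(dtype=int)
    )

    locus_rows = []
    cov_rows = []
    if len(alignments):
        for (contig, strand), grp in alignments.groupby(["contig", "strand"]):
            grp = grp.sort_values(["start", "end"])
            current: list[pd.Series] = []
            cur_end = None

            def flush(members: list, contig=contig, strand=strand):
                start = min(m.start for m in members)
                end = max(m.end for m in members)
                seqs = sorted({m.sequence for m in members})
                counts = pool_counts.loc[seqs, samples]
                cov = counts.sum(axis=0)
                total = float(cov.sum())
                multi = [s for s in seqs if placements_per_seq.get(s, 0) > 1]
                multi_cov = float(pool_counts.loc[multi, samples].sum().sum()) if multi else 0.0
                totals = counts.sum(axis=1)
                rep = totals.sort_values(ascending=False, kind="stable")
                rep = rep[rep == rep.iloc[0]].index.min()  # tie -> lexicographic
                locus_rows.append(
                    {
                        "contig": contig,
                        "start": int(start),
                        "end": int(end),
                        "strand": strand,
                        "representative_sequence": rep,
                        "member_count": len(seqs),
                        "total_coverage": int(total),
                        "multimap_fraction": (multi_cov / total) if total else 0.0,
                        "mitochondrial": contig in mito_contigs,
                    }
                )
                cov_rows.append(cov)

            for row in grp.itertuples():
                if current and row.start <= cur_end + merge_distance:
                    current.append(row)
                    cur_end = max(cur_end, row.end)
                else:
                    if current:
                        flush(current)
                    current = [row]
                    cur_end = row.end
            if current:
                flush(current)

    loci = pd.DataFrame(
        locus_rows,
        columns=[
            "contig", "start", "end", "strand", "representative_sequence",
            "member_count", "total_coverage", "multimap_fraction", "mitochondrial",
        ],
    )
    coverage = pd.DataFrame(cov_rows, columns=samples) if cov_rows else pd.DataFrame(columns=samples)
    if len(loci):
        order = loci.sort_values(["contig", "start", "strand"]).index
        loci = loci.loc[order].reset_index(drop=True)
        coverage = coverage.loc[order].reset_index(drop=True)
        keep = loci["total_coverage"] >= min_reads
        loci, coverage = loci[keep].reset_index(drop=True), coverage[keep].reset_index(drop=True)
        ids = [f"piR_LLi_{i + 1}" for i in range(len(loci))]
        loci.insert(0, "locus_id", ids)
        coverage.index = pd.Index(ids, name="feature_id")
    else:
        loci.insert(0, "locus_id", pd.Series(dtype=str))
        coverage.index.name = "feature_id"
    return loci, coverage
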