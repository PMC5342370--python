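"""Genomic-context annotation of piRNA placements and loci.

Each genomic placement is assigned exactly one category — 5'UTR, CDS, 3'UTR,
intron or intergenic — by overlap against gene models, with exon categories
taking precedence over introns and a >= 50% overlap requirement (robust to
boundary jitter).  Orientation records whether the read strand matches the
host transcript; cluster membership and nuclear/mitochondrial contig class
are annotated alongside.  Coordinates are 0-based half-open throughout.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

#: category precedence: exonic (5'UTR > CDS > 3'UTR) > intron
PRECEDENCE = {"five_prime_utr": 0, "CDS": 1, "three_prime_utr": 2, "intron": 3}
INTERGENIC = "intergenic"

ANNOTATION_COLUMNS = [
    "feature_id", "contig", "start", "end", "strand",
    "category", "host_transcript", "orientation", "in_cluster", "contig_class",
]


def build_region_index(gene_models: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in gene_models.itertuples():
        trees.setdefault(r.contig, IntervalTree()).addi(
            r.start, r.end, (r.feature, r.transcript_id, r.strand)
        )
    return trees


def _cluster_index(clusters: pd.DataFrame | None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    if clusters is not None:
        for r in clusters.itertuples():
            trees.setdefault(r.contig, IntervalTree()).addi(r.start, r.end, True)
    return trees


def annotate_placements(
    placements: pd.DataFrame,
    gene_models: pd.DataFrame,
    clusters: pd.DataFrame | None = None,
    mito_contigs: Sequence[str] = (),
    contig_lengths: Mapping[str, int] | None = None,
    min_overlap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Assign one context category per placement.

    ``placements`` needs columns feature_id, contig, start, end, strand.  A
    gene-model region is a candidate host when it covers at least
    ``min_overlap_fraction`` of the placement; among candidates the highest
    precedence category wins (ties broken by transcript id).  Placements with
    no candidate are intergenic with no host and orientation NA.
    """
    trees = build_region_index(gene_models)
    ctrees = _cluster_index(clusters)
    rows = []
    for r in placements.itertuples():
        if contig_lengths is not None:
            if r.contig not in contig_lengths:
                raise ValueError(f"placement contig {r.contig!r} not in genome")
            if r.start < 0 or r.end > contig_lengths[r.contig]:
                raise ValueError(
                    f"placement {r.contig}:{r.start}-{r.end} outside contig bounds"
                )
        length = r.end - r.start
        best = None
        tree = trees.get(r.contig)
        if tree is not None:
            for iv in tree.overlap(r.start, r.end):
                overlap = min(iv.end, r.end) - max(iv.begin, r.start)
                if overlap < min_overlap_fraction * length:
                    continue
                feature, tid, tstrand = iv.data
                key = (PRECEDENCE[feature], tid)
                if best is None or key < best[0]:
                    best = (key, feature, tid, tstrand)
        if best is None:
            category, host, orientation = INTERGENIC, "", "NA"
        else:
            _, category, host, tstrand = best
            orientation = "sense" if r.strand == tstrand else "antisense"
        ctree = ctrees.get(r.contig)
        in_cluster = bool(ctree is not None and ctree.overlap(r.start, r.end))
        rows.append(
            {
                "feature_id": r.feature_id,
                "contig": r.contig,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "category": category,
                "host_transcript": host,
                "orientation": orientation,
                "in_cluster": in_cluster,
                "contig_class": "mitochondrial-like" if r.contig in mito_contigs else "nuclear",
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def best_placement_per_feature(annotations: pd.DataFrame) -> pd.DataFrame:
    """One row per feature: the precedence-ranked best placement (category
    precedence, then (contig, start) for reproducibility)."""
    if annotations.empty:
        return annotations.copy()
    rank = annotations["category"].map(lambda c: PRECEDENCE.get(c, 4))
    ordered = annotations.assign(_rank=rank).sort_values(
        ["feature_id", "_rank", "contig", "start"]
    )
    return ordered.drop_duplicates("feature_id").drop(columns="_rank").reset_index(drop=True)


def _pct(counts: pd.Series) -> pd.DataFrame:
    total = counts.sum()
    return pd.DataFrame(
        {"count": counts, "percent": 100.0 * counts / total if total else 0.0}
    )


def context_summary(annotations: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Distribution tables: category, orientation-within-category, cluster
    membership, per-contig counts, contig class, intragenic share."""
    cats = ["five_prime_utr", "CDS", "intron", "three_prime_utr", INTERGENIC]
    by_cat = annotations["category"].value_counts().reindex(cats, fill_value=0)
    orient = (
        annotations[annotations["category"] != INTERGENIC]
        .groupby(["category", "orientation"])
        .size()
        .unstack(fill_value=0)
    )
    cluster = annotations["in_cluster"].value_counts().reindex([True, False], fill_value=0)
    cluster.index = ["in_cluster", "outside_cluster"]
    per_contig = annotations["contig"].value_counts().sort_index()
    contig_class = annotations["contig_class"].value_counts()
    n = len(annotations)
    intragenic = int((annotations["category"] != INTERGENIC).sum())
    overall = pd.DataFrame(
        {
            "count": [n, intragenic, n - intragenic],
            "percent": [100.0, 100.0 * intragenic / n if n else 0.0,
                        100.0 * (n - intragenic) / n if n else 0.0],
        },
        index=["total", "intragenic", "intergenic"],
    )
    return {
        "by_category": _pct(by_cat),
        "orientation": orient,
        "cluster": _pct(cluster),
        "per_contig": _pct(per_contig),
        "contig_class": _pct(contig_class),
        "overall": overall,
    }
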