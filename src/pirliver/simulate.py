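"""Synthetic small-RNA sequencing study generator.

Builds a fully self-contained toy study of liver piRNA profiling: a random
genome with gene models (5'UTR / CDS / intron / 3'UTR on both strands plus a
small mitochondrial-like contig), a known sncRNA annotation (piRNAs plus
miRNA/rRNA/tRNA/snoRNA decoys), per-stage negative-binomial read counts with
matched cirrhotic/tumor patients, adapter-trimmed FASTQ reads, and mRNA-like
transcripts carrying planted piRNA target sites.  Every planted quantity is
recorded in a :class:`GroundTruth` so downstream stages can be verified by
recomputation.

The statistical structure mirrors a bulk small-RNA-seq study of stepwise
hepatocarcinogenesis: five histological stages (CN, LGDN, HGDN, eHCC, pHCC),
a dominant low-expression tail in the piRNA repertoire, a 5'-uridine bias in
piRNA-sized sequences (primary-pathway biogenesis: no position-10 adenine
preference), and a configurable fraction of features with a planted fold
change between cirrhotic and tumor stages.

All outputs are pure functions of :class:`SimConfig`, including its seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io
from .util import hamming, revcomp

STAGES = ("CN", "LGDN", "HGDN", "eHCC", "pHCC")
#: stage sizes of the emulated study design (55 samples from 17 patients)
DEFAULT_SAMPLES_PER_STAGE = {"CN": 14, "LGDN": 9, "HGDN": 6, "eHCC": 6, "pHCC": 20}

DECOY_CLASSES = ("miRNA", "rRNA", "tRNA", "snoRNA")
DECOY_LENGTH_RANGES = {
    "miRNA": (21, 23),
    "rRNA": (28, 34),
    "tRNA": (30, 36),
    "snoRNA": (26, 32),
}

BASES = "ACGT"
MITO_CONTIG = "chrM_toy"

#: mean of a "low expression tail" feature, as a fraction of nb_mean
LOW_EXPRESSION_FACTOR = 1e-3

# Order-1 Markov composition of piRNA-like sequences (rows: from-base A,C,G,T;
# columns: to-base A,C,G,T).  The dinucleotide structure is what the k-mer
# discriminant learns; shuffling a sequence destroys it while preserving
# mononucleotide content.
PIRNA_TRANSITIONS = np.array(
    [
        [0.10, 0.10, 0.55, 0.25],
        [0.45, 0.10, 0.10, 0.35],
        [0.25, 0.40, 0.25, 0.10],
        [0.10, 0.35, 0.45, 0.10],
    ]
)

#: genomic-context mix used when embedding piRNA-like features, roughly the
#: intragenic/intergenic split reported for somatic liver piRNAs
EMBED_WEIGHTS = {
    "intron": 0.31,
    "CDS": 0.07,
    "five_prime_utr": 0.11,
    "three_prime_utr": 0.15,
    "intergenic": 0.30,
    "mito": 0.06,
}

REGION_FEATURES = ("five_prime_utr", "CDS", "intron", "three_prime_utr")


class SizingError(ValueError):
    """A contig is too short to host the requested annotation."""


@dataclass
class SimConfig:
    """Knobs of the synthetic study.  Same seed => byte-identical outputs."""

    seed: int = 0
    n_contigs: int = 4
    contig_length: int = 120_000
    mito_length: int = 16_000
    n_genes: int = 24
    n_known_pirnas: int = 60
    n_decoy_sncrnas: int = 25          # per decoy class
    n_planted_loci: int = 24
    n_samples_per_stage: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLES_PER_STAGE)
    )
    nb_mean: float = 50.0              # expected counts of an expressed feature
    nb_dispersion: float = 5.0         # NB size parameter; larger -> Poisson
    planted_fc: float = 4.0            # fold change of differential features
    frac_differential: float = 0.3
    frac_low_expression: float = 0.8   # "few sequence reads" tail
    u1_prob: float = 0.8               # P(piRNA-like sequence starts with T)
    read_length_range: tuple[int, int] = (25, 35)
    pirna_length_range: tuple[int, int] = (25, 35)
    locus_length_range: tuple[int, int] = (60, 100)
    n_transcripts: int = 30
    transcript_length: int = 1000
    planted_site_mismatches: Sequence[int] = (0, 1, 2, 3)
    de_stages: tuple[str, str] = ("CN", "pHCC")

    def __post_init__(self) -> None:
        lo, hi = self.read_length_range
        if not (18 <= lo <= hi <= 40):
            raise ValueError(f"read_length_range must lie within [18, 40], got {self.read_length_range}")
        plo, phi = self.pirna_length_range
        if not (25 <= plo <= phi <= 35):
            raise ValueError(f"pirna_length_range must lie within [25, 35], got {self.pirna_length_range}")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValueError("frac_differential must be in [0, 1]")
        if not 0.0 <= self.frac_low_expression <= 1.0:
            raise ValueError("frac_low_expression must be in [0, 1]")
        if not 0.0 <= self.u1_prob <= 1.0:
            raise ValueError("u1_prob must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for stage in self.n_samples_per_stage:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_samples_per_stage"] = dict(self.n_samples_per_stage)
        d["read_length_range"] = list(self.read_length_range)
        d["pirna_length_range"] = list(self.pirna_length_range)
        d["locus_length_range"] = list(self.locus_length_range)
        d["planted_site_mismatches"] = list(self.planted_site_mismatches)
        d["de_stages"] = list(self.de_stages)
        return d


@dataclass(frozen=True)
class Feature:
    """A simulated expressed feature: a known sncRNA or a planted locus.

    ``sequence`` is the read-strand sequence (for a locus, the full locus
    sequence from which reads are drawn).  Placed features carry their genomic
    interval and the annotation category they were embedded into.
    """

    feature_id: str
    kind: str  # 'piRNA', 'miRNA', 'rRNA', 'tRNA', 'snoRNA' or 'locus'
    sequence: str
    contig: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    category: str | None = None  # planted genomic context, or None


@dataclass
class GroundTruth:
    """Planted quantities, recorded for downstream verification."""

    differential: pd.DataFrame | None = None   # feature_id, direction, true_log2fc
    low_expressed: set[str] = field(default_factory=set)
    locus_intervals: pd.DataFrame | None = None
    target_sites: pd.DataFrame | None = None
    true_u1_prob: float | None = None

    @property
    def differential_feature_ids(self) -> set[str]:
        if self.differential is None or self.differential.empty:
            return set()
        return set(self.differential["feature_id"])


@dataclass
class Reference:
    """Generated reference bundle: genome, annotation, sncRNAs, transcripts."""

    genome: dict[str, str]
    gene_models: pd.DataFrame       # transcript_id, contig, strand, feature, start, end
    sncrnas: pd.DataFrame           # id, rna_class, sequence
    clusters: pd.DataFrame          # contig, start, end, name
    transcripts: dict[str, str]
    transcript_regions: pd.DataFrame  # transcript_id, utr5_end, cds_end, length
    features: list[Feature]
    mito_contig: str = MITO_CONTIG

    @property
    def known_pirnas(self) -> dict[str, str]:
        return {f.feature_id: f.sequence for f in self.features if f.kind == "piRNA"}

    @property
    def decoys(self) -> dict[str, str]:
        return {
            f.feature_id: f.sequence
            for f in self.features
            if f.kind in DECOY_CLASSES
        }

    @property
    def locus_truth(self) -> pd.DataFrame:
        rows = [
            {
                "feature_id": f.feature_id,
                "contig": f.contig,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "category": f.category,
            }
            for f in self.features
            if f.kind == "locus"
        ]
        return pd.DataFrame(
            rows, columns=["feature_id", "contig", "start", "end", "strand", "category"]
        )

    @property
    def placement_truth(self) -> pd.DataFrame:
        rows = [
            {
                "feature_id": f.feature_id,
                "contig": f.contig,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "category": f.category,
                "kind": f.kind,
            }
            for f in self.features
            if f.contig is not None
        ]
        return pd.DataFrame(
            rows,
            columns=["feature_id", "contig", "start", "end", "strand", "category", "kind"],
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(self.genome, outdir / "genome.fa")
        io.write_table(self.gene_models, outdir / "gene_models.tsv", index=False)
        io.write_fasta(
            [(f"{r.id}|{r.rna_class}", r.sequence) for r in self.sncrnas.itertuples()],
            outdir / "sncrnas.fa",
        )
        clusters = self.clusters.assign(score=0, strand=".")
        io.write_bed(clusters, outdir / "clusters.bed")
        io.write_fasta(self.transcripts, outdir / "transcripts.fa")
        io.write_table(self.transcript_regions, outdir / "transcript_regions.tsv", index=False)


# ---------------------------------------------------------------------------
# sequence models


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def pirna_like_seq(rng: np.random.Generator, length: int, u1_prob: float) -> str:
    """One piRNA-like sequence: 5'-U bias then the order-1 Markov composition."""
    cum = PIRNA_TRANSITIONS.cumsum(axis=1)
    out = []
    if rng.random() < u1_prob:
        out.append(3)  # T
    else:
        out.append(int(rng.integers(0, 3)))  # A, C or G
    u = rng.random(length - 1)
    for t in range(length - 1):
        out.append(int(np.searchsorted(cum[out[-1]], u[t], side="right")))
    return "".join(BASES[i] for i in out)


def pirna_like_seqs(
    rng: np.random.Generator,
    n: int,
    u1_prob: float,
    length_range: tuple[int, int] = (25, 35),
) -> list[str]:
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, n)
    return [pirna_like_seq(rng, int(L), u1_prob) for L in lengths]


# ---------------------------------------------------------------------------
# reference generation


def _make_gene(rng: np.random.Generator, transcript_id: str, contig: str,
               offset: int, strand: str) -> tuple[list[dict], int]:
    """Lay out one gene at ``offset``; returns (region rows, genomic length)."""
    u5 = int(rng.integers(80, 151))
    u3 = int(rng.integers(100, 201))
    n_exons = int(rng.integers(2, 4))
    exon_lens = [int(x) for x in rng.integers(120, 301, n_exons)]
    intron_lens = [int(x) for x in rng.integers(200, 601, n_exons - 1)]

    # 5'->3' order of region blocks
    blocks: list[tuple[str, int]] = [("five_prime_utr", u5)]
    for i, ex in enumerate(exon_lens):
        blocks.append(("CDS", ex))
        if i < len(intron_lens):
            blocks.append(("intron", intron_lens[i]))
    blocks.append(("three_prime_utr", u3))
    if strand == "-":
        blocks = blocks[::-1]  # genomic left-to-right

    rows = []
    pos = offset
    for feature, length in blocks:
        rows.append(
            {
                "transcript_id": transcript_id,
                "contig": contig,
                "strand": strand,
                "feature": feature,
                "start": pos,
                "end": pos + length,
            }
        )
        pos += length
    return rows, pos - offset


def _category_intervals(gene_models: pd.DataFrame, contig_lengths: Mapping[str, int],
                        margin: int = 500) -> dict[str, list[tuple[str, int, int, str]]]:
    """Plantable intervals per category, incl. intergenic complement."""
    cats: dict[str, list[tuple[str, int, int, str]]] = {c: [] for c in REGION_FEATURES}
    cats["intergenic"] = []
    for r in gene_models.itertuples():
        cats[r.feature].append((r.contig, r.start, r.end, r.strand))
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}
    if len(gene_models):
        for tid, grp in gene_models.groupby("transcript_id"):
            contig = grp["contig"].iloc[0]
            spans[contig].append((grp["start"].min(), grp["end"].max()))
    for contig, length in contig_lengths.items():
        if contig == MITO_CONTIG:
            continue
        cursor = margin
        for s, e in sorted(spans[contig]):
            if s - cursor >= 100:
                cats["intergenic"].append((contig, cursor, s, "."))
            cursor = e
        if length - margin - cursor >= 100:
            cats["intergenic"].append((contig, cursor, length - margin, "."))
    return cats


def generate_reference(config: SimConfig) -> Reference:
    """Generate genome, gene models, known sncRNA set, clusters and transcripts.

    Known piRNAs and planted piRNA-like loci are embedded into the genome at
    intervals drawn across annotation categories (5'UTR, CDS, intron, 3'UTR,
    intergenic and the mitochondrial-like contig) so every genomic-context
    category is exercised; intragenic placements are predominantly on the
    transcribed strand.
    """
    rng = np.random.default_rng([config.seed, 11])

    nuclear = [f"chr{i + 1}" for i in range(config.n_contigs)]
    genome: dict[str, bytearray] = {
        c: bytearray(random_seq(rng, config.contig_length), "ascii") for c in nuclear
    }
    genome[MITO_CONTIG] = bytearray(random_seq(rng, config.mito_length), "ascii")
    contig_lengths = {c: len(s) for c, s in genome.items()}

    # --- gene models ------------------------------------------------------
    margin = 1000
    cursors = {c: margin for c in nuclear}
    rows: list[dict] = []
    for g in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        tid = f"G{g:03d}"
        placed = False
        for c in sorted(nuclear, key=lambda c: cursors[c]):
            gene_rows, length = _make_gene(rng, tid, c, cursors[c], strand)
            if cursors[c] + length + margin <= contig_lengths[c]:
                rows.extend(gene_rows)
                cursors[c] += length + int(rng.integers(800, 2001))
                placed = True
                break
        if not placed:
            raise SizingError(
                f"contigs of length {config.contig_length} cannot host {config.n_genes} genes"
            )
    gene_models = pd.DataFrame(
        rows, columns=["transcript_id", "contig", "strand", "feature", "start", "end"]
    )

    cats = _category_intervals(gene_models, contig_lengths)
    cat_names = [c for c in EMBED_WEIGHTS if c == "mito" or cats.get(c)]
    cat_probs = np.array([EMBED_WEIGHTS[c] for c in cat_names])
    cat_probs = cat_probs / cat_probs.sum()

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}

    def place(seqlen: int) -> tuple[str, int, str, str | None, str]:
        """Pick (contig, start, strand, host_strand, category) for a new feature."""
        for _ in range(500):
            category = str(rng.choice(cat_names, p=cat_probs))
            if category == "mito":
                contig = MITO_CONTIG
                lo, hi = 100, contig_lengths[contig] - seqlen - 100
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi))
                strand = "+" if rng.random() < 0.5 else "-"
                host_strand = None
            else:
                pool = [iv for iv in cats[category] if iv[2] - iv[1] >= seqlen]
                if not pool:
                    continue
                contig, s, e, istrand = pool[int(rng.integers(0, len(pool)))]
                start = s + int(rng.integers(0, e - s - seqlen + 1))
                if category == "intergenic":
                    strand = "+" if rng.random() < 0.5 else "-"
                    host_strand = None
                else:
                    # mostly the transcribed strand, like somatic intronic piRNAs
                    strand = istrand if rng.random() < 0.95 else ("-" if istrand == "+" else "+")
                    host_strand = istrand
            if all(start + seqlen <= s or start >= e for s, e in occupied[contig]):
                occupied[contig].append((start, start + seqlen))
                return contig, start, strand, host_strand, category
        raise SizingError("could not find free space for a planted feature")

    def embed(seq: str, contig: str, start: int, strand: str) -> None:
        written = seq if strand == "+" else revcomp(seq)
        genome[contig][start : start + len(seq)] = written.encode("ascii")

    features: list[Feature] = []
    seen_seqs: set[str] = set()

    for i in range(config.n_known_pirnas):
        L = int(rng.integers(config.pirna_length_range[0], config.pirna_length_range[1] + 1))
        seq = pirna_like_seq(rng, L, config.u1_prob)
        while seq in seen_seqs:
            seq = pirna_like_seq(rng, L, config.u1_prob)
        seen_seqs.add(seq)
        contig, start, strand, _, category = place(L)
        embed(seq, contig, start, strand)
        features.append(
            Feature(f"piR_S{i:04d}", "piRNA", seq, contig, start, start + L, strand,
                    "mitochondrial" if category == "mito" else category)
        )

    for i in range(config.n_planted_loci):
        L = int(rng.integers(config.locus_length_range[0], config.locus_length_range[1] + 1))
        seq = pirna_like_seq(rng, L, config.u1_prob)
        contig, start, strand, _, category = place(L)
        embed(seq, contig, start, strand)
        features.append(
            Feature(f"locus_{i:03d}", "locus", seq, contig, start, start + L, strand,
                    "mitochondrial" if category == "mito" else category)
        )

    for cls in DECOY_CLASSES:
        lo, hi = DECOY_LENGTH_RANGES[cls]
        for i in range(config.n_decoy_sncrnas):
            seq = random_seq(rng, int(rng.integers(lo, hi + 1)))
            while seq in seen_seqs:
                seq = random_seq(rng, int(rng.integers(lo, hi + 1)))
            seen_seqs.add(seq)
            features.append(Feature(f"{cls}_S{i:03d}", cls, seq))

    sncrna_rows = [
        {"id": f.feature_id, "rna_class": f.kind, "sequence": f.sequence}
        for f in features
        if f.kind != "locus"
    ]
    sncrnas = pd.DataFrame(sncrna_rows, columns=["id", "rna_class", "sequence"])

    # --- piRNA clusters: one window around an intergenic planted feature,
    # one empty window, so cluster membership is exercised both ways.
    cluster_rows = []
    intergenic_feats = [f for f in features if f.category == "intergenic" and f.contig]
    if intergenic_feats:
        f0 = intergenic_feats[0]
        s = max(0, f0.start - 400)
        cluster_rows.append(
            {"contig": f0.contig, "start": s, "end": min(contig_lengths[f0.contig], f0.end + 400),
             "name": "cluster_1"}
        )
    free = [iv for iv in cats.get("intergenic", []) if iv[2] - iv[1] >= 1500]
    for contig, s, e, _ in free:
        if all(oe <= s or os_ >= s + 1000 for os_, oe in occupied[contig]):
            cluster_rows.append(
                {"contig": contig, "start": s, "end": s + 1000, "name": "cluster_2"}
            )
            break
    clusters = pd.DataFrame(cluster_rows, columns=["contig", "start", "end", "name"])

    # --- transcripts for the target search ------------------------------
    transcripts: dict[str, str] = {}
    region_rows = []
    for i in range(config.n_transcripts):
        tid = f"T{i:03d}"
        transcripts[tid] = random_seq(rng, config.transcript_length)
        utr5_end = int(rng.integers(80, 201))
        cds_end = int(rng.integers(500, 801))
        region_rows.append(
            {"transcript_id": tid, "utr5_end": utr5_end, "cds_end": cds_end,
             "length": config.transcript_length}
        )
    transcript_regions = pd.DataFrame(
        region_rows, columns=["transcript_id", "utr5_end", "cds_end", "length"]
    )

    return Reference(
        genome={c: s.decode("ascii") for c, s in genome.items()},
        gene_models=gene_models,
        sncrnas=sncrnas,
        clusters=clusters,
        transcripts=transcripts,
        transcript_regions=transcript_regions,
        features=features,
    )


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    config: SimConfig,
    features: Sequence[Feature] | Sequence[str],
    stage_multipliers: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw per-sample counts for ``features`` under a gamma-Poisson (NB) model.

    A ``frac_differential`` fraction of features receives a mean fold change of
    ``planted_fc`` in every non-reference stage (half up, half down); a
    ``frac_low_expression`` fraction forms the near-zero tail.  The NB is
    parameterized by mean ``nb_mean`` and size ``nb_dispersion`` (variance
    ``m + m^2/r``), drawn as Poisson(Gamma(r, m/r)).

    ``stage_multipliers`` optionally overrides per-stage means of selected
    features (``{feature_id: {stage: multiplier}}``) for planting
    stage-restricted expression patterns.

    Returns (counts features x samples, sample sheet, ground truth).
    """
    if config.planted_fc <= 0:
        raise ValueError("planted_fc must be > 0")
    ids = [f.feature_id if isinstance(f, Feature) else str(f) for f in features]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature ids")

    stage_sizes = {s: int(n) for s, n in config.n_samples_per_stage.items() if n > 0}
    if sum(1 for n in stage_sizes.values() if n >= 2) < 2:
        raise ValueError("need at least 2 stages with at least 2 samples each")

    meta_rows = []
    n_cn = stage_sizes.get("CN", 0)
    for stage, n in stage_sizes.items():
        for i in range(n):
            if stage == "CN" or n_cn == 0:
                patient = f"P{i + 1:02d}"
            else:
                patient = f"P{(i % n_cn) + 1:02d}"  # matched with a CN sample
            meta_rows.append(
                {"sample": f"{stage}{i + 1:02d}", "patient": patient, "stage": stage}
            )
    meta = pd.DataFrame(meta_rows, columns=["sample", "patient", "stage"])

    rng = np.random.default_rng([config.seed, 23])
    n = len(ids)
    perm = rng.permutation(n)
    n_diff = int(round(config.frac_differential * n)) if config.planted_fc != 1 else 0
    n_low = min(int(round(config.frac_low_expression * n)), n - n_diff)
    diff_idx = perm[:n_diff]
    low_idx = perm[n_diff : n_diff + n_low]

    log2fc = np.zeros(n)
    signs = np.where(np.arange(n_diff) % 2 == 0, 1.0, -1.0)
    log2fc[diff_idx] = signs * np.log2(config.planted_fc)

    base = np.full(n, config.nb_mean)
    base[low_idx] = config.nb_mean * LOW_EXPRESSION_FACTOR

    ref_stage = config.de_stages[0]
    id_pos = {fid: i for i, fid in enumerate(ids)}
    means = np.empty((n, len(meta)))
    for j, row in enumerate(meta.itertuples()):
        col = base.copy()
        if row.stage != ref_stage:
            col = col * np.exp2(log2fc)
        if stage_multipliers:
            for fid, per_stage in stage_multipliers.items():
                if row.stage in per_stage:
                    col[id_pos[fid]] = base[id_pos[fid]] * per_stage[row.stage]
        means[:, j] = col

    r = config.nb_dispersion
    lam = rng.gamma(shape=r, scale=means / r)
    counts = pd.DataFrame(
        rng.poisson(lam), index=pd.Index(ids, name="feature_id"), columns=list(meta["sample"])
    )

    differential = pd.DataFrame(
        {
            "feature_id": [ids[i] for i in diff_idx],
            "direction": ["up" if log2fc[i] > 0 else "down" for i in diff_idx],
            "true_log2fc": [log2fc[i] for i in diff_idx],
        },
        columns=["feature_id", "direction", "true_log2fc"],
    ).sort_values("feature_id", ignore_index=True)

    truth = GroundTruth(
        differential=differential,
        low_expressed={ids[i] for i in low_idx},
        true_u1_prob=config.u1_prob,
    )
    return counts, meta, truth


# ---------------------------------------------------------------------------
# reads


def _locus_reads(rng: np.random.Generator, locus_seq: str, count: int,
                 length_range: tuple[int, int], u1_prob: float) -> list[str]:
    """``count`` reads tiled across the locus: first read anchored at the 5'
    end, last at the 3' end, intermediates evenly spaced (guarantees the read
    union reproduces the locus interval once coverage is adequate).

    Mimicking the 5'-uridine cutting preference of primary piRNA processing,
    each intermediate read start snaps, with probability ``u1_prob``, to the
    nearest T within 4 nt of its tiled position."""
    L = len(locus_seq)
    lo, hi = length_range
    lens = [min(int(x), L) for x in rng.integers(lo, hi + 1, count)]
    reads = []
    for i, ln in enumerate(lens):
        if count == 1 or i == 0:
            start = 0
        elif i == count - 1:
            start = L - ln
        else:
            start = int(round(i * (L - ln) / (count - 1)))
            if rng.random() < u1_prob:
                window = range(max(0, start - 4), min(L - ln, start + 4) + 1)
                t_pos = [s for s in window if locus_seq[s] == "T"]
                if t_pos:
                    start = min(t_pos, key=lambda s: (abs(s - start), s))
        reads.append(locus_seq[start : start + ln])
    return reads


def emit_reads(
    counts: pd.DataFrame,
    features: Sequence[Feature],
    config: SimConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write one adapter-trimmed FASTQ per sample (constant quality 'I').

    Known sncRNAs emit their annotated sequence count-many times; planted loci
    emit count-many reads drawn from the locus interval on the read strand.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmap = {f.feature_id: f for f in features}
    missing = [fid for fid in counts.index if fid not in fmap]
    if missing:
        raise ValueError(f"features without sequences: {missing[:5]}")

    paths: dict[str, Path] = {}
    for j, sample in enumerate(counts.columns):
        srng = np.random.default_rng([config.seed, 41, j])
        col = counts[sample].to_numpy()
        path = outdir / f"{sample}.fastq"

        def records():
            k = 0
            for fid, c in zip(counts.index, col):
                c = int(c)
                if c == 0:
                    continue
                f = fmap[fid]
                if f.kind == "locus":
                    seqs = _locus_reads(srng, f.sequence, c, config.read_length_range,
                                        config.u1_prob)
                else:
                    seqs = [f.sequence] * c
                for seq in seqs:
                    yield f"{sample}.{k}", seq
                    k += 1

        io.write_fastq(records(), path)
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# target-site planting


def _mutate(rng: np.random.Generator, seq: str, m: int) -> str:
    """Mutate exactly ``m`` distinct positions to a different base."""
    out = list(seq)
    for pos in rng.choice(len(seq), size=m, replace=False):
        choices = [b for b in BASES if b != out[pos]]
        out[pos] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def region_of(position: int, utr5_end: int, cds_end: int) -> str:
    if position < utr5_end:
        return "five_prime_utr"
    if position < cds_end:
        return "CDS"
    return "three_prime_utr"


def plant_target_sites(
    transcripts: Mapping[str, str],
    transcript_regions: pd.DataFrame,
    guide_pairs: Sequence[tuple[str, str, int]],
    seed: int = 0,
    detect_threshold: int = 3,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Overwrite 20-nt transcript windows with mutated reverse complements.

    ``guide_pairs`` is a sequence of (pirna_id, 20-nt guide, mismatches m):
    for each pair, a window of some transcript is replaced by the reverse
    complement of the guide mutated at exactly ``m`` positions, so the target
    search has known answers.  Sites with ``m > detect_threshold`` are
    recorded as undetectable at that threshold.
    """
    rng = np.random.default_rng([seed, 57])
    new = {tid: list(seq) for tid, seq in transcripts.items()}
    regions = transcript_regions.set_index("transcript_id")
    tids = sorted(new)
    occupied: dict[str, list[tuple[int, int]]] = {tid: [] for tid in tids}

    rows = []
    for i, (pid, guide, m) in enumerate(guide_pairs):
        if len(guide) != 20:
            raise ValueError(f"guide for {pid} is {len(guide)} nt, expected 20")
        if not 0 <= m <= 4:
            raise ValueError(f"mismatch count {m} outside the design range 0..4")
        window = _mutate(rng, revcomp(guide), m)
        assert hamming(guide, revcomp(window)) == m
        placed = False
        for _ in range(200):
            tid = tids[int(rng.integers(0, len(tids)))]
            L = len(new[tid])
            if L < 20:
                continue
            start = int(rng.integers(0, L - 20 + 1))
            if all(start + 20 <= s or start >= e for s, e in occupied[tid]):
                placed = True
                break
        if not placed:
            raise SizingError("could not place a target site without overlap")
        occupied[tid].append((start, start + 20))
        new[tid][start : start + 20] = window
        r = regions.loc[tid]
        rows.append(
            {
                "pirna_id": pid,
                "transcript_id": tid,
                "start": start,
                "end": start + 20,
                "mismatches": m,
                "region": region_of(start + 10, int(r["utr5_end"]), int(r["cds_end"])),
                "detectable": m <= detect_threshold,
            }
        )
    sites = pd.DataFrame(
        rows,
        columns=["pirna_id", "transcript_id", "start", "end", "mismatches", "region", "detectable"],
    )
    return {tid: "".join(chars) for tid, chars in new.items()}, sites
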