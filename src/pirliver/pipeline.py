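"""End-to-end orchestration: simulate -> classify -> discover -> normalize ->
de -> stages -> features -> context -> targets -> cluster.

Every stage writes plain-text tables under the output directory and appends
a record count to the manifest; a rerun with the same configuration produces
byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__, classify, cluster, context, discovery, expression
from . import io, seqfeatures, simulate, targets
from .simulate import MITO_CONTIG, Reference, SimConfig

logger = logging.getLogger("pirliver")

STAGE_NAMES = (
    "simulate", "classify", "discover", "normalize", "de",
    "stages", "features", "context", "targets", "cluster",
)


@dataclass
class PipelineConfig:
    """Run parameters: the simulation plus every analysis threshold."""

    sim: SimConfig = field(default_factory=SimConfig)
    collapse_window: tuple[int, int] = (18, 40)
    class_priority: tuple[str, ...] = classify.DEFAULT_PRIORITY
    discovery_window: tuple[int, int] = (25, 35)
    score_threshold: float = 0.5
    merge_distance: int = 0
    max_placements: int = 30
    min_locus_reads: int = 1
    cpm_threshold: float = 1.0
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    stage_alpha: float = 0.05
    high_rpm_cutoff: float = 5000.0
    max_target_mismatches: int = 3
    n_planted_guides: int = 4
    heatmap_pseudocount: float = 1.0
    cluster_k: int = 2
    paired: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name == "sim":
                continue
            if f.name in raw:
                val = raw.pop(f.name)
                if isinstance(val, list):
                    val = tuple(val)
                kwargs[f.name] = val
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(sim=sim, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["collapse_window"] = list(self.collapse_window)
        d["discovery_window"] = list(self.discovery_window)
        d["class_priority"] = list(self.class_priority)
        return d


def _write_summary_tables(tables: dict[str, pd.DataFrame], outdir: Path, prefix: str) -> None:
    for name, table in tables.items():
        io.write_table(pd.DataFrame(table), outdir / f"{prefix}_{name}.tsv")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all ten stages; returns (and writes) the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def done(name: str, records: int) -> None:
        logger.info("stage %-9s complete: %d records", name, records)
        stages.append({"name": name, "records": int(records)})

    try:
        # 1 -- simulate -----------------------------------------------------
        sim = config.sim
        ref = simulate.generate_reference(sim)
        counts, meta, truth = simulate.simulate_counts(sim, ref.features)
        fastqs = simulate.emit_reads(counts, ref.features, sim, outdir / "reads")

        guide_pairs = []
        planted_pirnas = [
            f for f in ref.features if f.kind == "piRNA" and len(f.sequence) >= 21
        ][: config.n_planted_guides]
        for f in planted_pirnas:
            guide, _ = targets.extract_guide(f.sequence)
            for m in sim.planted_site_mismatches:
                guide_pairs.append((f.feature_id, guide, m))
        transcripts, site_truth = simulate.plant_target_sites(
            ref.transcripts, ref.transcript_regions, guide_pairs, seed=sim.seed,
            detect_threshold=config.max_target_mismatches,
        )
        ref = dataclasses.replace(ref, transcripts=transcripts)
        truth.locus_intervals = ref.locus_truth
        truth.target_sites = site_truth

        refdir = outdir / "reference"
        ref.write(refdir)
        truthdir = outdir / "truth"
        truthdir.mkdir(exist_ok=True)
        io.write_table(counts, truthdir / "true_counts.tsv")
        io.write_table(meta, truthdir / "sample_sheet.tsv", index=False)
        io.write_table(truth.differential, truthdir / "differential.tsv", index=False)
        io.write_table(truth.locus_intervals, truthdir / "planted_loci.tsv", index=False)
        io.write_table(site_truth, truthdir / "planted_target_sites.tsv", index=False)
        io.write_table(ref.placement_truth, truthdir / "planted_placements.tsv", index=False)
        done("simulate", int(counts.to_numpy().sum()))

        # 2 -- classify -----------------------------------------------------
        cdir = outdir / "classify"
        cdir.mkdir(exist_ok=True)
        collapsed, discards = classify.collapse_fastq(fastqs, config.collapse_window)
        index = classify.AnnotationIndex.from_frame(ref.sncrnas, config.class_priority)
        assigned = classify.assign_classes(collapsed, index)
        pirna_counts = classify.pirna_count_matrix(assigned)
        detected, _ = classify.detection_report(pirna_counts, meta)
        pool = classify.unannotated_pool(assigned)
        library_sizes = collapsed[list(counts.columns)].sum(axis=0)
        io.write_table(assigned, cdir / "assigned.tsv")
        io.write_table(discards, cdir / "discards.tsv")
        io.write_table(pirna_counts, cdir / "pirna_counts.tsv")
        io.write_table(detected.to_frame(), cdir / "pirnas_detected_per_stage.tsv")
        io.write_table(classify.class_totals(assigned), cdir / "class_totals.tsv")
        io.write_table(pool, cdir / "unannotated_pool.tsv")
        io.write_table(library_sizes.rename("library_size").to_frame(),
                       cdir / "library_sizes.tsv")
        done("classify", len(collapsed))

        # 3 -- discover -----------------------------------------------------
        ddir = outdir / "discovery"
        ddir.mkdir(exist_ok=True)
        positives = sorted(ref.known_pirnas.values())
        negatives = sorted(ref.decoys.values())
        candidates, score_report = discovery.score_pirna_like(
            pool, positives, negatives, seed=sim.seed,
            threshold=config.score_threshold, length_window=config.discovery_window,
        )
        alignments, unmapped, repetitive = discovery.map_candidates(
            candidates, ref.genome, config.max_placements
        )
        loci, locus_cov = discovery.build_loci(
            alignments, candidates, config.merge_distance, config.min_locus_reads,
            mito_contigs=[MITO_CONTIG],
        )
        io.write_table(candidates, ddir / "candidates.tsv")
        io.write_table(alignments, ddir / "alignments.tsv", index=False)
        bed = loci.rename(columns={"locus_id": "name", "total_coverage": "score"})
        io.write_bed(bed, ddir / "loci.bed")
        io.write_table(loci, ddir / "loci.tsv", index=False)
        io.write_table(locus_cov, ddir / "locus_coverage.tsv")
        pd.Series(unmapped, name="sequence", dtype=str).to_csv(
            ddir / "unmapped.tsv", sep="\t", index=False)
        pd.Series(repetitive, name="sequence", dtype=str).to_csv(
            ddir / "repetitive.tsv", sep="\t", index=False)
        with open(ddir / "score_report.json", "w") as fh:
            json.dump(score_report, fh, indent=2, sort_keys=True)
        done("discover", len(loci))

        # 4 -- normalize ----------------------------------------------------
        ndir = outdir / "expression"
        ndir.mkdir(exist_ok=True)
        rpm_pirna = expression.normalize_rpm(pirna_counts, library_sizes)
        rpm_locus = expression.normalize_rpm(locus_cov, library_sizes)
        kept_p, rm_p = expression.filter_low_expression(rpm_pirna, meta, config.cpm_threshold)
        kept_l, rm_l = expression.filter_low_expression(rpm_locus, meta, config.cpm_threshold)
        rpm_pirna_f, rpm_locus_f = rpm_pirna.loc[kept_p], rpm_locus.loc[kept_l]
        io.write_table(rpm_pirna, ndir / "pirna_rpm.tsv")
        io.write_table(rpm_locus, ndir / "locus_rpm.tsv")
        io.write_table(rm_p, ndir / "pirna_low_expression_removed.tsv")
        io.write_table(rm_l, ndir / "locus_low_expression_removed.tsv")
        hi, share = expression.flag_high_expression(rpm_pirna, meta, config.high_rpm_cutoff)
        io.write_table(
            pd.DataFrame({"feature_id": hi}).assign(rpm_share_of_total=share),
            ndir / "high_expression.tsv", index=False)
        done("normalize", len(rpm_pirna_f) + len(rpm_locus_f))

        # 5 -- de -----------------------------------------------------------
        ga, gb = sim.de_stages
        de_frames = {}
        for family, mat in (("pirna", rpm_pirna_f), ("locus", rpm_locus_f)):
            # BH adjusted within each family, mirroring separate signatures
            de = expression.wilcoxon_de(
                mat, meta, ga, gb, config.fc_threshold, config.fdr_threshold,
                paired=config.paired,
            )
            de_frames[family] = de
            io.write_table(de, ndir / f"de_{family}.tsv")
        n_sig = int(sum(df["in_signature"].sum() for df in de_frames.values()))
        done("de", n_sig)

        # 6 -- stages -------------------------------------------------------
        combined = pd.concat([rpm_pirna_f, rpm_locus_f])
        have_all = all(
            s in set(meta["stage"]) for s in ("CN", "pHCC", *expression.INTERMEDIATE_STAGES)
        )
        if have_all and len(combined):
            patterns = expression.stage_patterns(combined, meta, config.stage_alpha)
        else:
            patterns = pd.DataFrame()
        io.write_table(patterns, ndir / "stage_patterns.tsv")
        done("stages", len(patterns))

        # 7 -- features -----------------------------------------------------
        fdir = outdir / "features"
        fdir.mkdir(exist_ok=True)
        pirna_seqs = sorted(ref.known_pirnas.values())
        # one sequence per discovered locus: its most abundant member read
        lli_seqs = sorted(loci["representative_sequence"])
        comp_pirna = seqfeatures.positional_composition(pirna_seqs)
        io.write_table(comp_pirna, fdir / "composition_pirna.tsv")
        bias_rows = [seqfeatures.biogenesis_report(pirna_seqs).assign(set="piRNA")]
        if lli_seqs:
            comp_cand = seqfeatures.positional_composition(lli_seqs)
            io.write_table(comp_cand, fdir / "composition_pirna_like.tsv")
            bias_rows.append(seqfeatures.biogenesis_report(lli_seqs).assign(set="piRNA-like"))
        bias = pd.concat(bias_rows, ignore_index=True)
        io.write_table(bias, fdir / "biogenesis_bias.tsv", index=False)
        done("features", len(bias))

        # 8 -- context ------------------------------------------------------
        xdir = outdir / "context"
        xdir.mkdir(exist_ok=True)
        pirna_tbl = pd.DataFrame(
            {"sequence": list(ref.known_pirnas.values())},
            index=pd.Index(list(ref.known_pirnas.values())),
        )
        pirna_aln, _, _ = discovery.map_candidates(pirna_tbl, ref.genome, config.max_placements)
        seq_to_id = {v: k for k, v in ref.known_pirnas.items()}
        pirna_placements = pirna_aln.assign(
            feature_id=pirna_aln["sequence"].map(seq_to_id)
        )[["feature_id", "contig", "start", "end", "strand"]]
        locus_placements = loci.rename(columns={"locus_id": "feature_id"})[
            ["feature_id", "contig", "start", "end", "strand"]
        ]
        contig_lengths = {c: len(s) for c, s in ref.genome.items()}
        for label, plc in (("pirna", pirna_placements), ("locus", locus_placements)):
            ann = context.annotate_placements(
                plc, ref.gene_models, ref.clusters, mito_contigs=[MITO_CONTIG],
                contig_lengths=contig_lengths,
            )
            io.write_table(ann, xdir / f"{label}_annotations.tsv", index=False)
            io.write_table(context.best_placement_per_feature(ann),
                           xdir / f"{label}_best_placement.tsv", index=False)
            _write_summary_tables(context.context_summary(ann), xdir, label)
        done("context", len(pirna_placements) + len(locus_placements))

        # 9 -- targets ------------------------------------------------------
        tdir = outdir / "targets"
        tdir.mkdir(exist_ok=True)
        guide_sources = dict(ref.known_pirnas)
        guide_sources.update(
            dict(zip(loci["locus_id"], loci["representative_sequence"]))
        )
        guides, skipped = targets.extract_guides(guide_sources)
        sites = targets.find_sites(
            guides, ref.transcripts, ref.transcript_regions, config.max_target_mismatches
        )
        summary = targets.target_summary(sites)
        io.write_table(sites, tdir / "sites.tsv", index=False)
        io.write_table(skipped, tdir / "skipped_guides.tsv", index=False)
        io.write_table(summary["region_counts"].rename("n_sites").to_frame(),
                       tdir / "region_counts.tsv")
        io.write_table(summary["pair_site_counts"], tdir / "pair_site_counts.tsv", index=False)
        scalars = {k: v for k, v in summary.items() if isinstance(v, int)}
        with open(tdir / "summary.json", "w") as fh:
            json.dump(scalars, fh, indent=2, sort_keys=True)
        done("targets", len(sites))

        # 10 -- cluster -----------------------------------------------------
        kdir = outdir / "cluster"
        kdir.mkdir(exist_ok=True)
        signature = [
            fid for df in de_frames.values() for fid in df.index[df["in_signature"]]
        ]
        feature_set = signature if len(signature) >= 2 else list(combined.index)
        try:
            dist = cluster.kendall_distance(combined, feature_set)
        except ValueError:
            feature_set = list(combined.index)
            dist = cluster.kendall_distance(combined, feature_set)
        tree = cluster.ward_cluster(dist)
        labels = tree.labels(config.cluster_k)
        heat = cluster.export_heatmap_table(combined, feature_set, config.heatmap_pseudocount)
        io.write_table(dist, kdir / "distance.tsv")
        io.write_table(labels.to_frame(), kdir / "labels.tsv")
        io.write_table(heat, kdir / "heatmap.tsv")
        pd.DataFrame(tree.linkage).to_csv(kdir / "linkage.tsv", sep="\t",
                                          index=False, header=False)
        (kdir / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
        done("cluster", len(labels))
    except Exception as exc:
        stage_name = STAGE_NAMES[len(stages)] if len(stages) < len(STAGE_NAMES) else "?"
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    manifest = {
        "pirliver_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "seed": config.sim.seed,
        "parameters": config.to_dict(),
        "stages": stages,
        "notes": [
            "Ward linkage applied to the 1 - Kendall tau-b dissimilarity "
            "directly (non-Euclidean; standard approximation).",
            "RPM library size = reads passing ingest filters per sample.",
        ],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
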