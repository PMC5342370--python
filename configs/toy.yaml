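# Bundled toy study configuration for `pirliver all`.
# The simulated design mirrors the emulated study: 55 samples over five
# histological stages (CN, LGDN, HGDN, eHCC, pHCC) with matched patients,
# a dominant low-expression tail, 5'-U-biased piRNA-sized reads, planted
# differential features, planted piRNA-like loci and planted target sites.
sim:
  seed: 20160713
  n_contigs: 4
  contig_length: 120000
  mito_length: 16000
  n_genes: 24
  n_known_pirnas: 60
  n_decoy_sncrnas: 25
  n_planted_loci: 24
  n_samples_per_stage: {CN: 14, LGDN: 9, HGDN: 6, eHCC: 6, pHCC: 20}
  nb_mean: 50.0
  nb_dispersion: 5.0
  planted_fc: 4.0
  frac_differential: 0.3
  frac_low_expression: 0.8
  u1_prob: 0.8
  read_length_range: [25, 35]
  n_transcripts: 30
  planted_site_mismatches: [0, 1, 2, 3]

collapse_window: [18, 40]
discovery_window: [25, 35]
score_threshold: 0.5
merge_distance: 0
max_placements: 30
cpm_threshold: 1.0
fc_threshold: 1.5
fdr_threshold: 0.05
stage_alpha: 0.05
high_rpm_cutoff: 5000.0
max_target_mismatches: 3
cluster_k: 2
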