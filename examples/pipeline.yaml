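# Fully synthetic demo pipeline: simulate a 44-sample cohort, map cis-eQTLs,
# build LD proxies, score replication against a simulated validation study,
# run both GWAS-enrichment directions and the Mendelian gene-set test.
#   epiqtl run-all --config examples/pipeline.yaml --seed 7
out_dir: demo_run
simulate:
  n_chroms: 2
  snps_per_chrom: 500
  n_genes: 100
  frac_true_eqtl_genes: 0.2
  gwas_enrichment_odds: 10.0
  gwas_beta_a: 0.01
  n_gwas_true_snps: 100
  validation_replication_rate: 0.3
  validation_background_rate: 0.002
  geneset_enrichment_odds: 10.0
  n_mendelian_epilepsy_genes: 15
  n_mendelian_other_genes: 30
cis_window_bp: 20000
eqtl_fdr_cut: 0.05
ld_r2_threshold: 0.8
proxy_r2_threshold: 0.8
n_permutations: 1999
perm_gwas_threshold: 0.0001
min_bin: 10
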