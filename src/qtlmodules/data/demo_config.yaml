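# Bundled demonstration study: 3 tissues, 80 variants in 16 LD blocks,
# 90 genes carrying 3 planted co-expression modules, planted cis/trans
# eQTLs, three colocalization scenarios and a 5-set pathway catalog.
simulation:
  n_samples: 300
  n_variants: 80
  ld_block_size: 5
  within_block_r2: 0.9
  maf_range: [0.2, 0.5]
  n_tissues: 3
  n_genes: 90
  n_modules: 3
  module_size: 15
  module_factor_sd: 4.0
  noise_sd: 1.0
  inverse_normal: true
  planted_eqtls:
    - {variant_id: v0003, gene_id: g0001, tissue_ids: [tissue01, tissue02, tissue03], beta: 3.0, kind: cis}
    - {variant_id: v0018, gene_id: g0016, tissue_ids: [tissue01, tissue02], beta: 3.0, kind: cis}
    - {variant_id: v0033, gene_id: g0031, tissue_ids: [tissue01], beta: 3.0, kind: cis}
    - {variant_id: v0043, gene_id: g0050, tissue_ids: [tissue01, tissue02, tissue03], beta: 0.8, kind: cis}
    - {variant_id: v0060, gene_id: g0055, tissue_ids: [tissue01], beta: 0.8, kind: cis}
    - {variant_id: v0060, gene_id: g0055, tissue_ids: [tissue02], beta: -0.8, kind: cis}
    - {variant_id: v0070, gene_id: g0060, tissue_ids: [tissue01], beta: 1.0, kind: trans}
  coloc_scenarios:
    - name: shared
      region_variants: &region [v0041, v0042, v0043, v0044, v0045, v0046, v0047, v0048, v0049, v0050,
                                v0051, v0052, v0053, v0054, v0055, v0056, v0057, v0058, v0059, v0060]
      causal_variant_trait1: v0045
      causal_variant_trait2: v0045
      shared: true
      beta1: 0.9
      beta2: 0.9
      n1: 300
      n2: 300
      trait2_kind: protein
    - name: distinct
      region_variants: *region
      causal_variant_trait1: v0048
      causal_variant_trait2: v0057
      shared: false
      beta1: 0.9
      beta2: 0.9
      n1: 300
      n2: 300
      trait2_kind: metabolite
    - name: h0_null
      region_variants: *region
      causal_variant_trait1: null
      causal_variant_trait2: null
      shared: false
      beta1: 0.0
      beta2: 0.0
      n1: 300
      n2: 300
      trait2_kind: protein
  pathways:
    - {name: pw_module1, mode: module, module_index: 1}
    - {name: pw_module2, mode: module, module_index: 2}
    - {name: pw_partial3, mode: partial, module_index: 3, size: 15, overlap: 0.6}
    - {name: pw_random1, mode: random, size: 20}
    - {name: pw_random2, mode: random, size: 12}
  seed: 11
cis_window_bp: 1000000
permutations: 1000
fdr: 0.05
r2_min: 0.8
ld_window_bp: 1000000
rho_min: 0.8
signed_coexpression: false
gap_kmax: 6
gap_B: 50
gap_rule: globalSEmax
fixed_alpha: 5.0e-8
h4_threshold: 0.9
coloc_p1: 1.0e-4
coloc_p2: 1.0e-4
coloc_p12: 1.0e-5
coloc_prior_sd: 0.15
enrich_alpha: 0.05
seed: 11
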