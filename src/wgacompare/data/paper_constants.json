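{
  "assembly_size_fn": 270300000,
  "assembly_size_fv": 220400000,
  "te_total_len_fn": 117216089,
  "te_total_len_fv": 76805372,
  "class1_len_fn": 57063567,
  "class1_len_fv": 49183869,
  "class2_len_fn": 46284298,
  "tir_len_fn": 36948539,
  "tir_len_fv": 16869199,
  "ltr_len_fn": 44737372,
  "line_len_fn": 8315089,
  "sine_len_fn": 195484,
  "snp_total": 4561825,
  "indel_total": 846301,
  "kmer_number": 17016192556,
  "kmer_peak_depth": 57,
  "gene_total": 28780,
  "go_bp_genes": 9890,
  "go_mf_genes": 9534,
  "go_cc_genes": 6395
}
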