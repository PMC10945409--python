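# Full-defaults pipeline configuration template.
# Pass to `ampatlas report --config <file>`; every key is optional and
# defaults to the value shown.
seed: 0
id_min: 0.5          # family-edge alignment identity threshold
cov_min: 0.6         # family-edge coverage threshold
f_min: 3             # minimum pure-species clade size for founder calls
detect_frac: 0.01    # per-cell-type expression detection fraction
min_cells: 3         # per-cell-type detection floor (cells)
upstream_bp: 2500    # ATAC promoter-priming window (bp upstream of TSS)
sigma_threshold: 0.5 # mean-sigma candidate cutoff
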