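# Example pipeline configuration for `coloc3d run --config pipeline.toml`.
# Paths are resolved relative to the working directory.

model = "model.tsv"            # 3D model table: chromosome, bp, x, y, z
features = "genes.gff3"        # GFF3 (or BED with feature_format = "bed")
regulons = "regulons.tsv"      # TSV with columns tf, target, evidence
outdir = "coloc3d_out"         # results.tsv + report.json land here

feature_format = "gff3"
feature_class = "gene"         # keep only records of this GFF3 type
evidence = ["binding"]         # evidence classes to keep
min_targets = 2                # modules below this matched size are skipped
n_bins = 100                   # background histogram bins
block_size = 512               # rows per distance-computation chunk
seed = 0
log_level = "INFO"
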