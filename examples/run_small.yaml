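# Pipeline settings for the small synthetic experiment. Generate the inputs
# first with:  raregene simulate --config examples/synthetic_small.yaml --outdir data
matrix: data/matrix.tsv
annotation: data/annotation.tsv
cells: data/cells.tsv
normals: data/normals.tsv
coverage: data/coverage.tsv
gene_sets:
  stemness: data/gene_sets/stemness.txt
  g1s: data/gene_sets/g1s.txt
  g2m: data/gene_sets/g2m.txt
  invasion1: data/gene_sets/invasion1.txt
  invasion2: data/gene_sets/invasion2.txt
  invasion3: data/gene_sets/invasion3.txt
  invasion4: data/gene_sets/invasion4.txt
outdir: run_small
min_genes: 100        # the small matrix has ~1100 genes; the 3000 default fits full annotations
max_sample_prop: 0.5  # ~12 cells per sample here; at the default 0.2 a single extra cell trips the filter
n_perm: 200
seed: 7
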