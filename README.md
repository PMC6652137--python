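# genopanel

Identify the closest accessions in a crop germplasm collection for a
single-sample whole-genome resequencing result (a variant-only VCF),
without shipping the full genotype matrix around: the collection is
compressed once into a low-dimensional PCA **reference panel**, and any
query is projected through the frozen parameters and placed among the
accessions with ranked distances and a complete-linkage dendrogram.

## What it does

1. **build** — ingest a multi-accession genotype table (TSV dialect or
   multi-sample VCF), encode diploid genotypes as alternate-allele
   dosages {0,1,2}, drop sites with minor-allele frequency below a
   threshold (default 0.2) or call rate below 50%, mean-impute missing
   calls, center, and fit a deterministic full-SVD PCA (default 20
   components) with accessions as observations. The result — site
   index, site means, loadings, explained-variance ratios, and the
   accession score matrix — is saved as a single `.v2g` archive.
2. **query** — read a single-sample, *variant-only* VCF, align it to the
   panel's site index, and project it through the pre-trained
   parameters. Panel sites absent from the VCF are scored homozygous
   reference (dosage 0): variant-only callers omit hom-ref sites, so
   absence is a call. Allele conflicts and no-calls are scored missing
   and imputed at the site mean. Outputs: a ranked distance table
   (Euclidean, PC space), a newick tree, and a dendrogram (SVG) with
   the query leaf highlighted.
3. **update** — integrate new accessions into an existing panel by
   projecting them through the frozen model (no refit); score columns
   are appended, label collisions get `_2`/`_3` suffixes.
4. **simulate** — generate a structured synthetic collection (diverged
   populations via the Balding–Nichols construction, pedigree cross
   offspring, redundant copies, missing calls) plus matched
   variant-only query VCFs, fully reproducible by seed. This is how the
   test suite exercises everything with no downloads.

Chromosome names are normalized at every ingestion point (`Gm01` ≡
`chr1` ≡ `01` ≡ `1`), so panels and queries from different pipelines
interoperate.

## CLI

```sh
genopanel --seed 42 simulate --pops 3 --fst 0.2 --sites 5000 --per-pop 20 --out sim/
genopanel build  --genotypes sim/genotypes.tsv --maf 0.2 --components 20 \
                 --groups sim/groups.tsv --out panel.v2g
genopanel query  --panel panel.v2g --vcf sim/queries/P1_A1.vcf --out report/
genopanel update --panel panel.v2g --genotypes new_accessions.tsv --out panel2.v2g
```

`query` writes `report/distances.tsv` (rank, label, distance, group),
`report/tree.nwk`, `report/dendrogram.svg` and `report/placement.json`.
Global flags: `--log-level`, `--seed`, `--config file.yaml` (keys:
`maf`, `components`, `k`, `call_rate_floor`, `linkage`). Failures exit
with a category-specific code (3 parameter, 4 input format, 5 panel
version, 6 incompatibility, 7 empty panel) and print one
machine-parseable `error:<category>\t<message>` line.

## Genotype TSV dialect

Header `chrom  pos  ref  alt  <label1> <label2> ...`; one row per
biallelic SNP; cells are alternate-allele dosages `0`/`1`/`2` or `NA`.

## Panel archive format (`.v2g`, version 1)

An uncompressed ZIP containing `metadata.json` (format version,
parameters, explained-variance ratios, labels, groups, provenance) and
delimited text blocks `sites.tsv`, `site_means.txt`, `loadings.tsv`,
`scores.tsv`. Floats are written with 17 significant digits, so
save → load → save is byte-identical.

## Library use

```python
import genopanel as gp

table, truth = gp.simulate_collection(gp.SimConfig(seed=42))
panel = gp.fit_panel(table, maf_threshold=0.2, n_components=20)
gp.save_panel(panel, "panel.v2g")

profile = gp.read_query_vcf("sample.vcf", panel.model)
profile = gp.project_query(panel.model, profile)
report = gp.rank_distances(panel, profile.scores, k=10)
tree = gp.build_tree(panel, profile)
print(report.closest, gp.to_newick(tree))
```
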