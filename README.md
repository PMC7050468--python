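# synbiogeo

Biogeography of hot-spring *Synechococcus* populations from `psaA` amplicon
variants: how much of the variation among island-like microbial communities
is explained by geographic isolation, and how much by water chemistry?

Hot springs behave like islands for thermophilic cyanobacteria. Given
per-sample amplicon reads, sample/spring metadata, and a putative-ecotype
(PE) demarcation, this package:

1. **Dereplicates** reads into high-frequency sequence (HFS) tables —
   distinct 302-bp variants with ≥ N identical reads across all samples
   (HFS10 for most analyses, HFS2 for dispersal) — and splits variants into
   the A-like and B′-like lineages by exact identity to reference segments.
2. **Measures distance decay of sharing**: for every sample pair, the
   percentage of shared variants, `100 · 2|Sa∩Sb| / (|Sa|+|Sb|)`, the
   shared-read count in the smaller library, and the haversine great-circle
   distance (replicates use a 1 m convention), with a least-squares trend
   of sharing against log₁₀ distance and a permutation p-value.
3. **Classifies PE endemism** on read abundances: endemic (100% of reads in
   one basin), near-endemic (≥ 90%), or multi-basin, with orthogonal flags
   for predominant (> 1% of some sample) and cosmopolitan (> 10 reads per
   sample in ≥ 2 basins) PEs.
4. **Fits constrained ordinations (CCA)** from first principles — the
   chi-square residual matrix `Q̄ = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}` is
   projected onto row-weighted environmental predictors and decomposed by
   SVD — with marginal constrained variability per parameter, forward
   stepwise selection under a max-pseudo-F permutation test, per-PE
   cluster-tightness permutation p-values, and abundance-weighted density
   curves along any parameter's biplot arrow.
5. **Simulates** spring archipelagos with planted ecotypes (Gaussian niches
   on z-scored chemistry × endemic/regional/cosmopolitan dispersal
   kernels, founder-effect variant proportions, multinomial reads), so the
   entire pipeline is testable against known truth with no downloads.

The bundled survey tables (28 mat samples from 18 springs in 7 geothermal
basins across Yellowstone, Montana and Oregon, with 18 candidate
physical/chemical parameters) provide the real-world schema and the inputs
for the geographic helpers. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

Generate a synthetic archipelago and run the full pipeline:

```sh
synbiogeo simulate --seed 1 --out demo
cat > demo.yaml <<CFG
reads: demo/reads.fasta
samples: demo/samples.tsv
springs: demo/springs.tsv
references: demo/references.fasta
truth_variants: demo/truth_variants.tsv
demarcation: truth_labels
outdir: demo_out
seed: 1
CFG
synbiogeo run-all --config demo.yaml
```

The manifest summarizes each stage. With seed 1 this prints (abridged):

```
hfs:        reads_in 46406, variants 82, hfs10 66, hfs2 80
sharing:    pairs 861, decay_slope -11.75, decay_p 0.001
endemism:   pes 21, predominant 18, endemic 14
ordination: selected [CaCO, temperature, Cl, S2, latitude, Mg, pH, longitude]
            total_inertia 4.304, constrained_inertia 3.539
```

Reading the numbers: 46,406 reads collapse to 82 distinct variants, 66 of
which pass the HFS10 threshold. Percent sharing falls by ~11.7 points per
decade of distance (permutation p = 0.001) — the planted dispersal
limitation is recovered. Fourteen of 21 detected ecotypes are endemic to
one basin, and stepwise CCA keeps eight of the ten candidate parameters,
led by the chemistry gradients the niche model was planted on. Per-table
outputs (`sharing.tsv`, `endemism.tsv`, `stepwise.tsv`, `tightness.tsv`,
`density.tsv`, …) land in `demo_out/`, each with a provenance header.

Library use mirrors the CLI:

```python
from synbiogeo import SimConfig, write_dataset, RunConfig, run_pipeline
paths = write_dataset("demo", SimConfig(seed=1))
manifest = run_pipeline(RunConfig(reads=str(paths["reads"]), ...))
```

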