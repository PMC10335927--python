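# lcimpute

Genotype imputation for low-coverage whole-genome sequencing data, built
around four ideas:

- **Sparse reference panel** (`lcimpute.panel_store`): common variants
  (panel MAF ≥ 0.001 by default) are stored one bit per haplotype; rare
  variants store only the sorted minor-allele carrier indices, with a
  per-haplotype transpose for direct access to each haplotype's rare
  alleles. Panel, genetic map and PBWT checkpoints serialize to a single
  self-describing binary file (no general-purpose compression).
- **Sparse PBWT** (`lcimpute.sparse_pbwt`): positional prefix arrays are
  maintained at common sites only; between two adjacent common variants a
  small PBWT runs over just the haplotypes carrying a minor allele in the
  interval and is spliced back — exactly reproducing the full site-by-site
  PBWT at every common site. Conditioning states (default K=2,000) are
  selected from prefix-array neighbors at ~0.1 cM checkpoints plus carrier
  sharing at confidently called rare alleles.
- **Polymorphic-site-restricted Li & Stephens HMM** (`lcimpute.ls_hmm`):
  forward–backward runs only at sites polymorphic within the K selected
  haplotypes, with transition probabilities adjusted to the genetic
  distance between consecutive polymorphic sites; monomorphic-site
  posteriors come from the emission alone. A numba kernel and a scalar
  numpy reference kernel are kept equivalent by test.
- **Gibbs sampler** (`lcimpute.imputation_engine`): initialization from
  rare-variant calls and two consecutive haploid imputation steps, then
  burn-in + main iterations alternating haploid imputation and phasing;
  genotype posteriors are averaged over main iterations. All randomness is
  counter-based (a pure function of seed, sample, iteration, haplotype and
  absolute site index), so output is bitwise deterministic and invariant
  to windowing and thread count. A scaffold pass imputes indels /
  low-quality variants into phased high-quality SNP haplotypes.

Supporting modules: `glcaller` (genotype likelihoods from pileups),
`concordance` (streaming frequency-binned Pearson r², NRD/NRC),
`simdata` (synthetic panels with a rare-heavy SFS, mosaic target
diplotypes, Poisson-coverage pileups) and `cli_pipeline` (chunking,
ligation, CLI).

## CLI

```bash
# synthetic dataset: panel.vcf, genetic.map, truth.vcf, target.gl.vcf, pileups
lcimpute simulate --n-hap 200 --n-site 2000 --region-bp 2000000 \
    --n-targets 4 --coverage 1.0 --seed 1 --out-dir sim/

# reference VCF + genetic map -> binary panel (sites, sparse columns,
# RLE-encoded PBWT checkpoints, map anchors)
lcimpute prepare-panel --vcf sim/panel.vcf --map sim/genetic.map --out panel.bin

# chunk table, per-chunk imputation, ligation
lcimpute chunk --panel panel.bin --window-cm 4.0 --buffer-cm 0.5
lcimpute impute --panel panel.bin --gl sim/target.gl.vcf --chunk-id 0 \
    --seed 9 --out chunk0.vcf
lcimpute impute --panel panel.bin --gl sim/target.gl.vcf --chunk-id 1 \
    --seed 9 --out chunk1.vcf
lcimpute ligate chunk0.vcf chunk1.vcf --panel panel.bin --out imputed.vcf

# frequency-binned r2 / NRD / NRC against truth
lcimpute concordance --truth sim/truth.vcf --imputed imputed.vcf
```

`impute` exposes `--K --ne --err --burnin --main --maf-threshold --seed
--threads`; results are independent of `--threads` by construction.

## Acceptance

The acceptance criteria are property-based and implemented one test per
criterion in `tests/test_acceptance.py` (sparse-PBWT oracle equivalence,
sparse-HMM equivalence, exhaustive-path oracle, coverage-graded genotype
recovery, binary round trips, concordance identities, chunk/ligate
consistency, bitwise determinism). The report script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs a fast end-to-end pipeline sanity check and writes the (empty)
numeric-target report; there are no externally reproducible headline
numbers at desk scale, so all quantitative checks live in the test suite.
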