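# snapmap

Linkage mapping and QTL analysis of an outbred snapdragon F2 cross
(*Antirrhinum barrelieri* × *A. rupestre*), from raw RAD-seq SNP calls to
species-origin genotypes, a de novo linkage map, transmission-ratio-distortion
and QTL scans, and a discriminant morphology index — plus a full cross
simulator used to validate every stage against known truth.

## Layout

- `src/snapmap/` — the package:
  - `core_io` — VCF / TSV / JSON readers and writers, `AnalysisConfig`
    (TOML), result provenance (config hash + seed).
  - `simcross` — outbred F2 cross simulator: founder haplotypes, Haldane
    crossovers, gametic transmission distortion, QTL and trichome traits,
    RAD-locus SNP emission with genotyping error and distal missingness;
    landscape, maternal-family and two-species character simulators.
  - `hapcall` — bins SNPs into RAD loci, infers ≤4 locus haplotypes by
    co-segregation, assigns parental species origin, recodes F2 genotypes
    as bb/br/rr.
  - `linkmap` — two-point ML recombination/LOD, grouping, greedy ordering,
    Kosambi map, Chakravarti genome coverage, TRD scan, marker-spacing and
    polymorphism-clustering calibration tests, restriction-motif utilities.
  - `qtlscan` — HMM genotype probabilities, Haley–Knott regression scans,
    permutation thresholds, stepwise additive models, LOD-drop intervals,
    exact binomial QTL-colocalization test.
  - `morpho` — character normalization, Fisher discriminant morphology
    index, PCA, maternal-family heritability, segregation and pooling
    checks, distance regressions of admixture and morphological
    intermediacy.
  - `cli` — `snapmap` command with subcommands
    `simulate | hapcall | map | trdscan | qtlscan | overlap | morpho | report`.
- `analysis/` — numbered thin drivers running the pipeline into `results/run/`.
- `scripts/acceptance.py` — computes the headline quantities as JSON:
  `python scripts/acceptance.py --seed 1 --out results/acceptance.json`.
- `tests/` — unit, property-based (hypothesis, derandomized), CLI and
  acceptance suites.
- `docs/methods.md` — statistical methods in detail.

## Install and run

```sh
pip install --no-build-isolation -e .
python -m pytest -q tests/
snapmap simulate --seed 1 --out-dir results/run
snapmap hapcall --vcf results/run/genotypes.vcf --roles results/run/roles.tsv \
    --out-genotypes results/run/species_genotypes.tsv
snapmap map --genotypes results/run/species_genotypes.tsv --out-map results/run/map.tsv
```

or run the numbered scripts in `analysis/` in order. Every output JSON
carries a provenance block (config hash, seed); reruns with the same seed are
byte-identical.

## Configuration

Thresholds live in one `AnalysisConfig` (overridable via `--config file.toml`):
SNP binning window 1.5 kb, max locus missingness 25%, grouping LOD 6,
ordering LOD 10, scan grid 1 cM, genotype error 0.001, α 0.05, 1000
permutations.
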