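# karyomap

Sex-specific linkage mapping, comparative map alignment and karyotype
rearrangement accounting for pedigree SNP data, with a full synthetic-data
stack so that every stage is testable offline.

The package builds female/male genetic maps from mixed full-/half-sib family
genotypes (two-point recombination fractions by EM over unknown parental
phases, LOD grouping, seriation ordering with reference-order tie-breaking,
Haldane/Kosambi distances), aligns two maps on shared markers, classifies
structural differences between them (Robertsonian and tandem fusions,
fissions, whole-arm translocations) using marker order and the male
telomere-concentrated recombination profile, and checks the implied
karyotype arithmetic (2n, NF, metacentric/acrocentric counts).

## Modules

| module | contents |
| --- | --- |
| `karyomap.karyotype` | chromosome pairs with arm structure, rearrangement operators, 2n/NF summaries, the 29-pair European-type reference and the bundled three-event set |
| `karyomap.simulate` | truth maps (with planted rearrangements), telomere-biased male crossover model, meiosis and pedigree genotype simulators, FISH-style probe co-location counts |
| `karyomap.mapping` | two-point EM (exact and vectorized all-pairs scan), grouping, ordering, map building, map summaries |
| `karyomap.compare` | shared-marker pairing, correspondence graph, event classification, fusion-architecture inference, karyotype prediction, comparison plots |
| `karyomap.io` / `karyomap.config` / `karyomap.cli` | TSV readers/writers, flat key=value config, `karyomap` command line |

## Command line

```sh
# simulate a query genome carrying the three standard rearrangements
karyomap simulate --config cfg.txt --events north-american --out-dir sim

# build the sex-specific linkage map from the simulated pedigree genotypes
karyomap map --config cfg.txt --genotypes sim/genotypes.tsv \
    --pedigree sim/pedigree.tsv --reference sim/reference_map.tsv --out map.tsv

# detect rearrangements against the reference map and predict the karyotype
karyomap compare --config cfg.txt --reference-map sim/reference_map.tsv \
    --query-map map.tsv --karyotype sim/reference_karyotype.tsv \
    --out-dir cmp --plots

# karyotype arithmetic only: 29 pairs / NF 74 -> 27 pairs / NF 72
karyomap karyotype --event-set north-american

# totals for any marker-table TSV
karyomap summarize --map map.tsv
```

`cfg.txt` is a flat `key = value` file (see `karyomap.config.PipelineConfig`
for keys, defaults and valid ranges); any omitted key takes its default.
Runs log the seed and a config digest to stderr, and identical config + seed
gives byte-identical outputs.

Map tables are 8-column TSVs: marker id, linkage group, 1-based order,
female cM, male cM, number of informative meioses, accession, and a
population-specific flag written as a literal `x` (or empty). The header row
is optional and auto-detected on read.

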