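# Methods

## Data model

The store keeps two tiers per dataset, mirroring how genotype warehouses
separate cheap-to-index variant facts from bulky genotype payloads:

- a **variant index** (sqlite) holding, per variant: sequence, 1-based
  position, variant type (SNP / INDEL / MNP / OTHER, a pure function of the
  allele set), number of known alleles, the allele list, and the sets of
  annotation consequence terms and gene names. All variant-level filters
  run against this index.
- **genotype runs** in gzipped JSON blobs of `chunk_size` variants
  (default 5000) in import order. A run stores, per individual, the
  genotype call (sorted allele-index multiset plus an informational phase
  flag), any numeric per-sample FORMAT values, and the parsed functional
  annotations. A missing genotype is stored by absence, which keeps sparse
  matrices compact and makes "missing" unambiguous.

Chunking is by import order with a fixed chunk size; incremental ingest
appends new chunks and never rewrites existing ones, so the final chunk of
an earlier ingest may stay short. The chunk is the unit of query
execution, caching, progress reporting and export buffering.

Annotation terms are duplicated into the variant index so that
annotation-only queries never touch the genotype blobs; the duplication is
tiny (two short string sets per variant).

## Query semantics

A query is one variant-level block plus up to two group blocks and a
discriminate flag. Decisions are made per variant:

1. the variant-level conjunction (type, allele-count bounds, sequence set,
   inclusive position window, consequence/gene membership) against the
   index;
2. per group: numeric-threshold **masking** (a call is treated as missing
   when any thresholded field is absent or below its minimum; stored data
   is untouched), then tallies — missing ratio, genotype counts, allele
   counts, MAF, major genotype — then the group filter;
3. with `discriminate`, both groups must pass "all or mostly the same" and
   their major genotypes must differ.

Conventions, chosen once and applied everywhere:

- **Inclusive comparisons.** Missing ratio passes at exactly its maximum,
  the major-genotype share passes at exactly the similarity ratio, MAF
  bounds are a closed interval, and position windows include both ends.
  This is the convention under which a 90% similarity / 10% missing query
  admits boundary cases.
- **Similarity denominator = called genotypes.** The similarity ratio is
  computed over post-masking non-missing calls only; missingness is
  governed solely by the missing-ratio control. This keeps the two knobs
  orthogonal. The alternative (denominator = all selected individuals)
  would conflate them; it is the main semantic fork a reimplementation of
  this kind of engine faces, and the one to revisit first when reconciling
  counts against another implementation at the threshold boundary.
- **Unphased genotype equality.** 0|1 and 1/0 are the same genotype for
  patterns and discrimination; phase is retained only for round-tripping.
- **MAF** generalizes min(p, 1−p): the frequency of the second-most-
  frequent allele, 0 for a monomorphic variant, undefined (and failing any
  MAF filter) when no call remains. Multi-allelic variants are filtered on
  the same statistic.
- **Major-genotype ties** break toward the lexicographically smallest
  allele multiset, for determinism.
- When two groups are present without `discriminate`, a variant must
  satisfy both blocks (conjunction).

## Execution, caching, concurrency

Chunks are evaluated independently and reassembled in chunk order, so the
result equals a single sequential pass regardless of scheduling. A bounded
thread pool (default: CPU count) evaluates chunks concurrently; threads
share no mutable state. Every execution produces the per-chunk match
counts in the same pass ("count at the same time"), so find never needs a
separate count query.

Counts are cached per chunk under a canonical query key — a SHA-256 of the
sorted-key JSON serialization of (dataset id, query), making the key
independent of how the query was spelled. A repeated count answers
entirely from the cache; a repeated find uses the cached per-chunk counts
to stop scanning each chunk once its known number of matches has been
emitted (and to skip empty chunks outright). Any ingest invalidates the
dataset's cache, since counts are stale after data change; the cache
otherwise persists across processes.

## Import/export

VCF reading is delegated to cyvcf2 (htslib): multi-allelic records stay
single records, haploid and diploid calls are both supported, and numeric
per-sample fields are auto-detected from FORMAT declarations with
`Number=1, Type=Integer|Float`. SnpEff `ANN` entries are parsed by fixed
subfield position, VEP `CSQ` by the header's `Format:` declaration with
`SYMBOL`→`Gene` fallback; `&`-joined consequence lists expand to one
annotation per term.

PLINK PED/MAP carries no reference allele, so the reference is the
alphabetically first observed allele — deterministic round trips were
preferred over biological truth, which the format cannot express. HapMap
is read and written in the common TASSEL dialect (two-letter cells, `NN`
missing); the strand column is stored verbatim, never applied, because
silent strand flipping is a classic corruption vector. HapMap export is
restricted to SNPs (skipped records are counted); PLINK export writes
missing as `0 0`. The Flapjack `.fjzip` container holds the project's flat
genotype-matrix and map formats under fixed member names `genotypes.txt`
and `map.txt`. Export decouples reading from writing through a bounded
four-chunk buffer with a dedicated reader thread.

Round trips are exact for the unphased genotype matrix, positions, allele
sets, numeric fields and annotations through VCF; PLINK and HapMap round
trips are exact up to the documented lossy aspects (phase, REF choice,
numeric fields, non-SNP records in HapMap).

## Synthetic data generator

The generator emulates the statistical structure the filters consume: per
variant an alternate-allele frequency drawn uniformly (default 0.05–0.5,
shared by all individuals, i.e. no group structure unless planted),
Hardy-Weinberg-style independent allele draws per diploid call, a missing
rate applied per call (default 5%), integer DP (5–60) and GQ (20–99) drawn
uniformly per sample, and SnpEff-style ANN strings on a fraction of
variants. Planted variants assign each group member its group's signature
genotype with probability `purity`, and planted calls of group members are
never masked missing — so a purity-1.0 plant passes a discrimination query
at similarity 1.0 and missing maximum 0 by construction. Generation is a
pure function of the spec (fixed draw order, single seeded generator):
identical seeds give byte-identical files. The truth table reports
*realized* tallies recomputed from the emitted genotypes, not the sampling
law.

What the generator does **not** emulate: linkage disequilibrium, allele-
frequency spectra from demography, genotyping-error correlation with
depth, or indel length distributions. Passing tests therefore demonstrate
the correctness of the query semantics on data with realistic missingness
and frequency ranges, not robustness to population structure.

## Test and verification scales

The oracle-equivalence and cache checks run 50 randomized queries over a
1000-variant × 50-individual dataset (the oracle is an independently
written sequential full scan in the test suite); round trips use 250 × 20;
planted recovery uses 10 pure plants among 5000 neutral variants at 50
individuals; the case/control emulation uses 222 individuals (144 vs 78)
with 1200 neutral variants over three chromosomes and 14 planted
sex-linked variants on one of them, 10 inside a 27.53–29.52 Mb window.
These sizes keep the full suite around a minute on one CPU while leaving
every code path (multi-chunk, multi-sequence, annotation, indel, cache,
concurrency) exercised. The published datasets such engines are typically
demonstrated on are orders of magnitude larger; nothing in the design is
size-limited except memory for one chunk of runs at a time.

## Known limitations

- Ploidy is limited to 1 and 2; polyploid calls are rejected at the call
  level.
- Partially missing diploid calls (`./1`) are treated as fully missing.
- The query engine materializes matching ids in memory in find mode; for
  datasets with hundreds of millions of matches a streaming find would be
  needed.
- The cache stores exact query keys only; no subsumption (a cached
  superset query does not accelerate a narrower one).
- PLINK chromosome codes are passed through verbatim; no recoding of
  numeric codes to names.
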