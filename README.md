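# genoquery

A chunked multi-sample genotype store with a two-group variant filter
engine, for exploring large SNP/indel call sets the way population
geneticists and breeders do: "show me the variants where most of my cases
share one genotype, most of my controls share a different one, with at most
10% missing data and decent read depth."

It is a command-line / library implementation of the query core found in
web-based genotype exploration portals: variants are imported from VCF (or PLINK
PED/MAP, or HapMap tables) into an embedded store that separates indexed
per-variant facts (sequence, position, type, allele count, functional
annotation) from bulky per-individual genotype runs, and queries are
evaluated chunk by chunk with per-chunk count caching, so repeated counts
are instant and interrupted browsing is cheap to resume.

## The filtering model

For a variant *v* and a group *G* of selected individuals, let the
*retained* calls be the genotypes of *G* at *v* that survive numeric
masking (a call is dropped when any thresholded per-sample field, e.g.
DP or GQ, is absent or below its minimum). Writing *n* = |G| and *c* for
the number of retained calls:

- **missing ratio** = (*n* − *c*) / *n*;
- **MAF** = frequency of the second-most-frequent allele among retained
  alleles (0 when monomorphic, undefined when *c* = 0);
- **major genotype** = the modal retained genotype under unphased
  comparison (0/1 ≡ 1|0), ties broken toward the smallest allele multiset;
- **similarity ratio** of the pattern "all or mostly the same" = (count of
  the major genotype) / *c*.

A group filter passes when missing ratio ≤ its maximum, MAF lies in its
closed interval, and (for the pattern) the major-genotype share is ≥ the
similarity threshold; all comparisons are inclusive. A **discriminate**
query requires both groups to pass "all or mostly the same" *and* their
major genotypes to differ — the quick case/control contrast that surfaces,
e.g., sex-linked loci when group 1 is the males and group 2 the females.

Variant-level conditions (type, allele count, sequence, position window,
SnpEff/VEP consequence terms and gene names) are evaluated first against
the index; genotype runs are only read when a group filter is present.

## Worked example

Generate a synthetic 12-individual dataset with two planted discriminating
variants, import it, and ask for variants separating the two halves of the
panel:

```
$ genoquery synth --individuals 12 --variants 60 --plant 2 --seed 9 \
      --out s.vcf --truth truth.tsv --metadata-out meta.tsv
wrote s.vcf: 62 variants x 12 individuals (2 planted)

$ genoquery import --format vcf --dataset demo --chunk-size 20 \
      --metadata meta.tsv s.vcf
imported 62 variants into 'demo' (4 new chunks)

$ cat q.txt
group1.individuals = ind0000,ind0001,ind0002,ind0003,ind0004,ind0005
group1.pattern = ALL_OR_MOSTLY_SAME
group1.ratio = 0.9
group1.max-missing = 0.2
group2.individuals = ind0006,ind0007,ind0008,ind0009,ind0010,ind0011
group2.pattern = ALL_OR_MOSTLY_SAME
group2.ratio = 0.9
group2.max-missing = 0.2
discriminate = true

$ genoquery query --dataset demo --query-file q.txt
matches: 2
sv000015
sv000026
```

The two matches are exactly the planted variants: in each, ≥ 90% of the
called genotypes within each group agree, fewer than 20% of each group's
calls are missing, and the two group majorities differ. Running the same
query again answers from the per-chunk count cache (`op=… cache hit` on
stderr). The result can be exported for the chosen individuals only:

```
$ genoquery export --dataset demo --format vcf --query-file q.txt --out sel.vcf
exported 2 variants x 12 individuals to sel.vcf

$ genoquery density --dataset demo --seq chr1 --start 1 --end 1000000 --bins 4
1       250000  10
250001  500000  11
500001  750000  14
750001  1000000 27
```

The density table bins variant counts over the interval (re-run with more
bins when zooming in); adding `--field DP` appends the cumulated read depth
of a selectable individual subset per bin.

## Store layout

One directory per dataset under the store root: `descriptor.json`
(individuals, chunk sizes, detected numeric fields), `variants.db` (sqlite
index of per-variant facts), `chunks/chunk_NNNNN.json.gz` (genotype runs,
5000 variants per chunk by default; missing genotypes stored by absence),
and `cache.json` (per-query per-chunk match counts, invalidated on ingest).
This layout is internal, not an interchange format — use the exporters.
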