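import random

import pytest

from genoquery import (
    GroupFilter,
    Query,
    SynthSpec,
    VariantLevelFilter,
    VariantStore,
    generate,
    read_vcf,
)


def build_dataset(tmp_path, spec: SynthSpec, chunk_size: int = 100, name: str = "ds"):
    """synth -> VCF -> import; returns (store, descriptor, in-memory records, gen)."""
    vcf = tmp_path / f"{name}.vcf"
    gen = generate(spec, vcf, truth_path=tmp_path / f"{name}.truth.tsv")
    imp = read_vcf(vcf)
    store = VariantStore(tmp_path / f"{name}_store")
    ds = store.create_dataset(name, imp.samples, chunk_size=chunk_size)
    store.ingest(ds, imp.records(), imp.numeric_fields, imp.annotation_source)
    records = list(store.iter_records(ds))
    return store, ds, records, gen


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """200 variants x 12 individuals with annotations, some indels, missing calls."""
    tmp = tmp_path_factory.mktemp("small")
    spec = SynthSpec(
        n_individuals=12,
        n_variants=200,
        sequences=(("chr1", 500_000), ("chr2", 300_000)),
        missing_rate=0.08,
        annotation_rate=0.3,
        indel_rate=0.1,
        seed=11,
    )
    return build_dataset(tmp, spec, chunk_size=32)


@pytest.fixture(scope="session")
def medium_dataset(tmp_path_factory):
    """1000 variants x 50 individuals, the oracle-equivalence test bed."""
    tmp = tmp_path_factory.mktemp("medium")
    spec = SynthSpec(
        n_individuals=50,
        n_variants=1000,
        sequences=(("chr1", 2_000_000), ("chr2", 1_000_000)),
        missing_rate=0.05,
        annotation_rate=0.25,
        indel_rate=0.05,
        seed=42,
    )
    return build_dataset(tmp, spec, chunk_size=128)


def random_query(rng: random.Random, individuals, sequences, numeric_fields) -> Query:
    """A randomized query mixing variant-level and group-level filters."""
    vf_kwargs = {}
    if rng.random() < 0.3:
        vf_kwargs["variant_types"] = frozenset(
            rng.sample(["SNP", "INDEL", "MNP", "OTHER"], rng.randint(1, 2))
        )
    if rng.random() < 0.3:
        vf_kwargs["sequences"] = frozenset(rng.sample(sequences, 1))
    if rng.random() < 0.3:
        lo = rng.randint(1, 500_000)
        vf_kwargs["position_min"] = lo
        vf_kwargs["position_max"] = lo + rng.randint(10_000, 1_000_000)
    if rng.random() < 0.2:
        vf_kwargs["effects"] = frozenset([rng.choice(["missense_variant", "stop_gained", "intron_variant"])])
    if rng.random() < 0.2:
        vf_kwargs["allele_count_min"] = 2
        vf_kwargs["allele_count_max"] = rng.randint(2, 3)

    def random_group():
        size = rng.randint(2, max(2, len(individuals) // 2))
        kwargs = {"individuals": tuple(rng.sample(individuals, size))}
        if rng.random() < 0.6:
            kwargs["pattern"] = "ALL_OR_MOSTLY_SAME"
            kwargs["similarity_ratio"] = rng.choice([0.5, 0.7, 0.9, 1.0])
        if rng.random() < 0.4:
            lo = round(rng.uniform(0.0, 0.3), 2)
            kwargs["maf_min"] = lo
            kwargs["maf_max"] = round(rng.uniform(lo, 0.5), 2)
        if rng.random() < 0.5:
            kwargs["max_missing_ratio"] = rng.choice([0.0, 0.1, 0.25, 0.5])
        if rng.random() < 0.4 and numeric_fields:
            f = rng.choice(sorted(numeric_fields))
            kwargs["numeric_thresholds"] = {f: rng.randint(5, 60)}
        return kwargs

    g1 = g2 = None
    discriminate = False
    roll = rng.random()
    if roll < 0.75:
        g1 = random_group()
    if roll < 0.45:
        g2 = random_group()
    if g1 and g2 and rng.random() < 0.4:
        g1["pattern"] = g2["pattern"] = "ALL_OR_MOSTLY_SAME"
        g1.setdefault("similarity_ratio", 0.8)
        g2.setdefault("similarity_ratio", 0.8)
        discriminate = True
    return Query(
        VariantLevelFilter(**vf_kwargs),
        GroupFilter(**g1) if g1 else None,
        GroupFilter(**g2) if g2 else None,
        discriminate,
    )
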