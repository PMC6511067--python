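import zipfile

import pytest

from genoquery import (
    GroupFilter,
    Query,
    SynthSpec,
    VariantLevelFilter,
    VariantStore,
    execute_query,
    export,
    read_hapmap,
    read_plink,
    read_vcf,
)
from conftest import build_dataset


def genotype_matrix(pairs, by_letters=False):
    """variant_id -> individual -> unphased genotype (indices or allele letters)."""
    out = {}
    for rec, run in pairs:
        row = {}
        for ind, call in run.calls.items():
            if by_letters:
                row[ind] = tuple(sorted(rec.known_alleles[i] for i in call.allele_indices))
            else:
                row[ind] = call.allele_indices
        out[rec.variant_id] = row
    return out


@pytest.fixture(scope="module")
def snp_dataset(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("export")
    spec = SynthSpec(n_individuals=10, n_variants=120, missing_rate=0.1,
                     annotation_rate=0.25, seed=21)
    return tmp, build_dataset(tmp, spec, chunk_size=40, name="snp")


def reimport(tmp, path, name, chunk_size=33):
    imp = read_vcf(path)
    store = VariantStore(tmp / f"{name}_store")
    ds = store.create_dataset(name, imp.samples, chunk_size=chunk_size)
    store.ingest(ds, imp.records(), imp.numeric_fields, imp.annotation_source)
    return store, ds


class TestVcfRoundTrip:
    def test_full_dataset_unphased_matrix_identical(self, snp_dataset):
        tmp, (store, ds, records, _) = snp_dataset
        out = tmp / "full.vcf"
        summary = export(store, ds, out, "vcf")
        assert summary.n_variants == ds.n_variants
        store2, ds2 = reimport(tmp, out, "re1")
        back = list(store2.iter_records(ds2))
        assert genotype_matrix(back) == genotype_matrix(records)
        # numeric fields and annotations survive too
        orig_dp = {rec.variant_id: run.numeric_values for rec, run in records}
        back_dp = {rec.variant_id: run.numeric_values for rec, run in back}
        assert back_dp == orig_dp
        orig_eff = {rec.variant_id: sorted(a.effect for a in run.annotations) for rec, run in records}
        back_eff = {rec.variant_id: sorted(a.effect for a in run.annotations) for rec, run in back}
        assert back_eff == orig_eff

    def test_individual_subset_export_has_exactly_those_columns(self, snp_dataset):
        tmp, (store, ds, records, _) = snp_dataset
        out = tmp / "subset.vcf"
        chosen = ds.individuals[3:5]
        export(store, ds, out, "vcf", individuals=chosen)
        header = [l for l in out.read_text().splitlines() if l.startswith("#CHROM")][0]
        assert header.split("\t")[9:] == chosen

    def test_query_filtered_export_row_count(self, snp_dataset):
        tmp, (store, ds, records, _) = snp_dataset
        q = Query(group1=GroupFilter(tuple(ds.individuals[:4]), "ALL_OR_MOSTLY_SAME", 0.7,
                                     max_missing_ratio=0.5))
        res = execute_query(store, ds, q, mode="find")
        out = tmp / "filtered.vcf"
        summary = export(store, ds, out, "vcf", variant_ids=res.variant_ids)
        assert summary.n_variants == res.total_count
        data_lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert len(data_lines) == res.total_count

    def test_empty_result_gives_valid_header_only_file(self, snp_dataset):
        tmp, (store, ds, _, _) = snp_dataset
        out = tmp / "empty.vcf"
        export(store, ds, out, "vcf", variant_ids=[])
        lines = out.read_text().splitlines()
        assert lines and all(l.startswith("#") for l in lines)
        imp = read_vcf(out)  # still a parseable VCF
        assert list(imp.records()) == []

    def test_gzip_output(self, snp_dataset):
        tmp, (store, ds, records, _) = snp_dataset
        out = tmp / "full.vcf.gz"
        export(store, ds, out, "vcf")
        store2, ds2 = reimport(tmp, out, "regz")
        assert ds2.n_variants == ds.n_variants


class TestPlinkRoundTrip:
    def test_allele_letter_matrix_preserved(self, snp_dataset):
        tmp, (store, ds, records, _) = snp_dataset
        base = tmp / "pl"
        summary = export(store, ds, base, "plink")
        assert set(summary.paths) == {str(base) + ".ped", str(base) + ".map"}
        inds, pairs = read_plink(str(base) + ".ped", str(base) + ".map")
        assert inds == ds.individuals
        assert genotype_matrix(pairs, by_letters=True) == genotype_matrix(records, by_letters=True)

    def test_missing_written_as_zero_zero(self, snp_dataset):
        tmp, (store, ds, records, _) = snp_dataset
        n_missing = sum(
            1 for rec, run in records for ind in ds.individuals if ind not in run.calls
        )
        ped = (tmp / "pl.ped").read_text()
        assert sum(row.split("\t")[6:].count("0") for row in ped.splitlines()) == 2 * n_missing


class TestHapmapRoundTrip:
    def test_snp_letter_matrix_preserved(self, snp_dataset):
        tmp, (store, ds, records, _) = snp_dataset
        out = tmp / "h.hapmap"
        export(store, ds, out, "hapmap")
        inds, pairs = read_hapmap(out)
        assert inds == ds.individuals
        assert genotype_matrix(pairs, by_letters=True) == genotype_matrix(records, by_letters=True)

    def test_indels_skipped_with_count(self, tmp_path):
        spec = SynthSpec(n_individuals=6, n_variants=60, indel_rate=0.4, seed=3)
        store, ds, records, _ = build_dataset(tmp_path, spec, chunk_size=25, name="mix")
        n_indels = sum(1 for rec, _ in records if rec.variant_type != "SNP")
        assert n_indels > 0
        out = tmp_path / "h.hapmap"
        summary = export(store, ds, out, "hapmap")
        assert summary.skipped == n_indels
        _, pairs = read_hapmap(out)
        assert len(pairs) == ds.n_variants - n_indels


class TestFlapjack:
    def test_fjzip_members_and_matrix_shape(self, snp_dataset):
        tmp, (store, ds, records, _) = snp_dataset
        out = tmp / "f.fjzip"
        chosen = ds.individuals[:2]
        export(store, ds, out, "flapjack", individuals=chosen)
        with zipfile.ZipFile(out) as zf:
            assert sorted(zf.namelist()) == ["genotypes.txt", "map.txt"]
            geno = zf.read("genotypes.txt").decode().splitlines()
            fjmap = zf.read("map.txt").decode().splitlines()
        assert geno[0] == "# fjFile = GENOTYPE"
        assert fjmap[0] == "# fjFile = MAP"
        assert len(geno) == 2 + len(chosen)  # marker header + one row per individual
        assert len(geno[1].split("\t")) == 1 + ds.n_variants
        assert len(fjmap) == 1 + ds.n_variants
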