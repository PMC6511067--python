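"""PLINK PED/MAP text reader.

The MAP file lists variants (chromosome, id, genetic distance, bp position);
the PED file has six leading columns (family, individual, father, mother,
sex, phenotype) followed by two allele columns per MAP variant.  ``0``
allele codes mean missing.  PLINK carries no reference allele, so the
reference is chosen deterministically as the alphabetically first observed
allele of each variant — documented so round trips are reproducible.
"""

from __future__ import annotations

from typing import Iterator

from ..model import GenotypeCall, GenotypeRun, ParseError, VariantRecord


def read_plink(ped_path, map_path) -> tuple[list[str], list[tuple[VariantRecord, GenotypeRun]]]:
    """Read a PED/MAP pair; returns (individual ids, (variant, run) list)."""
    variants = []  # (chrom, vid, pos)
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{map_path}: line {ln}: MAP needs 4 columns, got {len(parts)}")
            chrom, vid, _gd, pos = parts[:4]
            variants.append((chrom, vid, int(pos)))

    n_var = len(variants)
    individuals: list[str] = []
    genotypes: list[list[tuple[str, str]]] = []  # per individual, per variant allele pair
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_var:
                raise ParseError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * n_var} columns"
                    f" (6 + 2x{n_var} variants), got {len(parts)}"
                )
            individuals.append(parts[1])
            alleles = parts[6:]
            genotypes.append([(alleles[2 * i], alleles[2 * i + 1]) for i in range(n_var)])

    out = []
    for vi, (chrom, vid, pos) in enumerate(variants):
        observed = sorted(
            {a for row in genotypes for a in row[vi] if a != "0"}
        )  # alphabetically first observed allele becomes the reference
        if not observed:
            observed = ["N"]
        index = {a: i for i, a in enumerate(observed)}
        rec = VariantRecord(vid, chrom, pos, tuple(observed))
        calls = {}
        for ind, row in zip(individuals, genotypes):
            a1, a2 = row[vi]
            if a1 == "0" or a2 == "0":
                continue
            calls[ind] = GenotypeCall((index[a1], index[a2]))
        out.append((rec, GenotypeRun(vid, calls)))
    return individuals, out
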