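"""HapMap genotype table reader (TASSEL-style dialect).

Tab-delimited with 11 fixed leading columns (rs#, alleles, chrom, pos,
strand, assembly#, center, protLSID, assayLSID, panelLSID, QCcode) followed
by one column per individual.  Genotype cells are two IUPAC base letters
("AT"), a single letter for a haploid call, or "NN"/"N" for missing.  The
strand column is stored verbatim but never applied.
"""

from __future__ import annotations

from ..model import GenotypeCall, GenotypeRun, ParseError, VariantRecord

HAPMAP_COLUMNS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def read_hapmap(path) -> tuple[list[str], list[tuple[VariantRecord, GenotypeRun]]]:
    """Read a HapMap file; returns (individual ids, (variant, run) list)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [c.strip() for c in header[:11]] != HAPMAP_COLUMNS:
            raise ParseError(
                f"{path}: header does not start with the 11 fixed HapMap columns"
            )
        individuals = header[11:]
        out = []
        for ln, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 11 + len(individuals):
                raise ParseError(
                    f"{path}: line {ln}: expected {11 + len(individuals)} columns, got {len(parts)}"
                )
            vid, alleles_str, chrom, pos = parts[0], parts[1], parts[2], int(parts[3])
            declared = [a for a in alleles_str.split("/") if a and a != "N"]
            alleles = list(declared)
            index = {a: i for i, a in enumerate(alleles)}
            calls: dict[str, GenotypeCall] = {}
            for ind, cell in zip(individuals, parts[11:]):
                cell = cell.strip().upper()
                if cell in ("NN", "N", "", "--"):
                    continue
                letters = list(cell)
                if not all(c in "ACGT" for c in letters) or len(letters) > 2:
                    raise ParseError(f"{path}: line {ln}: bad genotype cell {cell!r} for {ind}")
                idxs = []
                for c in letters:
                    if c not in index:  # observed allele not declared: append
                        index[c] = len(alleles)
                        alleles.append(c)
                    idxs.append(index[c])
                calls[ind] = GenotypeCall(tuple(idxs))
            rec = VariantRecord(vid, chrom, pos, tuple(alleles) if alleles else ("N",))
            out.append((rec, GenotypeRun(vid, calls)))
    return individuals, out
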