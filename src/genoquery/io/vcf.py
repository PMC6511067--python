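"""VCF reader built on cyvcf2, yielding the store's (variant, run) stream.

Multi-allelic lines are kept as a single record with all ALT alleles.
Missing calls (``./.`` or ``.``) produce no call entry.  Per-sample FORMAT
fields declared with ``Number=1`` and ``Type=Integer|Float`` are detected
from the header and their values collected into each run; a sample whose
value is the htslib missing sentinel contributes nothing.  An INFO ``ANN``
declaration triggers SnpEff annotation parsing, ``CSQ`` triggers VEP
parsing using the header's ``Format: ...`` declaration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

from cyvcf2 import VCF

from ..model import GenotypeCall, GenotypeRun, ParseError, VariantRecord
from .annotations import csq_format_from_description, parse_snpeff_ann, parse_vep_csq

_INT_MISSING = -2147483648  # htslib int32 fill for absent values


@dataclass
class VcfImport:
    """Handle on an opened VCF: sample list, detected fields, record stream."""

    path: str
    samples: list[str]
    numeric_fields: dict[str, str]  # field name -> "Integer" | "Float"
    annotation_source: str  # none | snpeff | vep
    csq_format: Optional[list[str]] = None
    _vcf: VCF = field(default=None, repr=False)

    def records(self) -> Iterator[tuple[VariantRecord, GenotypeRun]]:
        return _iter_records(self)


def read_vcf(path) -> VcfImport:
    """Open a VCF 4.x file (plain or gzip) for import.

    Raises if the file declares no GT FORMAT field — genotype-less VCFs
    carry nothing this store can hold.
    """
    vcf = VCF(str(path))
    numeric: dict[str, str] = {}
    has_gt = False
    annotation_source = "none"
    csq_format = None
    for h in vcf.header_iter():
        info = h.info()
        htype = info.get("HeaderType")
        hid = info.get("ID")
        if htype == "FORMAT":
            if hid == "GT":
                has_gt = True
            elif info.get("Number") == "1" and info.get("Type") in ("Integer", "Float"):
                numeric[hid] = info.get("Type")
        elif htype == "INFO":
            if hid == "ANN":
                annotation_source = "snpeff"
            elif hid == "CSQ":
                annotation_source = "vep"
                csq_format = csq_format_from_description(info.get("Description", ""))
    if not has_gt:
        raise ParseError(f"{path}: no GT field declared in FORMAT — unsupported file")
    return VcfImport(
        path=str(path),
        samples=list(vcf.samples),
        numeric_fields=numeric,
        annotation_source=annotation_source,
        csq_format=csq_format,
        _vcf=vcf,
    )


def _iter_records(imp: VcfImport) -> Iterator[tuple[VariantRecord, GenotypeRun]]:
    samples = imp.samples
    line_no = 0
    for var in imp._vcf:
        line_no += 1
        try:
            alleles = tuple([var.REF] + list(var.ALT))
            vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}_{var.REF}"
            rec = VariantRecord(vid, var.CHROM, var.POS, alleles)
            calls: dict[str, GenotypeCall] = {}
            for sample, geno in zip(samples, var.genotypes):
                allele_idx, phased = geno[:-1], bool(geno[-1])
                if any(a < 0 for a in allele_idx):
                    continue  # absence encodes missingness
                calls[sample] = GenotypeCall(tuple(allele_idx), phased)
            numeric: dict[str, dict[str, float]] = {}
            for fname, ftype in imp.numeric_fields.items():
                arr = var.format(fname)
                if arr is None:
                    continue
                for sample, val in zip(samples, arr):
                    v = val[0] if getattr(val, "__len__", None) else val
                    v = float(v)
                    if v == _INT_MISSING or math.isnan(v):
                        continue
                    numeric.setdefault(sample, {})[fname] = int(v) if ftype == "Integer" else v
            annotations = []
            if imp.annotation_source == "snpeff":
                ann = var.INFO.get("ANN")
                if ann:
                    annotations = parse_snpeff_ann(ann)
            elif imp.annotation_source == "vep":
                csq = var.INFO.get("CSQ")
                if csq:
                    annotations = parse_vep_csq(csq, imp.csq_format)
            yield rec, GenotypeRun(vid, calls, numeric, annotations)
        except ParseError:
            raise
        except Exception as e:  # surface the offending data line
            raise ParseError(f"{imp.path}: malformed data line {line_no}: {e}") from e
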