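"""Functional-annotation parsing for SnpEff (ANN) and VEP (CSQ) INFO fields.

Both encodings pack one entry per annotated allele/transcript, entries
separated by commas and subfields by pipes.  SnpEff's ANN subfield order is
fixed (Allele | Annotation | Annotation_Impact | Gene_Name | ...); VEP's CSQ
subfields are named in the VCF header's ``Format: ...`` declaration and are
mapped by name.  An ``&``-joined consequence list expands to one annotation
object per consequence term, sharing the other fields.
"""

from __future__ import annotations

import re
from typing import Sequence

from ..model import FunctionalAnnotation, ParseError


def parse_snpeff_ann(ann_value: str) -> list[FunctionalAnnotation]:
    """Parse a SnpEff ANN INFO value into annotation objects."""
    out: list[FunctionalAnnotation] = []
    for entry in ann_value.split(","):
        parts = entry.split("|")
        if len(parts) < 4:
            raise ParseError(f"SnpEff ANN entry has {len(parts)} subfields, expected >= 4: {entry!r}")
        allele, effects, impact, gene = parts[0], parts[1], parts[2], parts[3]
        for effect in effects.split("&"):
            out.append(FunctionalAnnotation(allele=allele, effect=effect, impact=impact, gene_name=gene))
    return out


def csq_format_from_description(description: str) -> list[str]:
    """Extract the CSQ subfield names from the header Description text."""
    m = re.search(r"Format:\s*([\w|]+)", description)
    if not m:
        raise ParseError(f"cannot find 'Format: ...' in CSQ description: {description!r}")
    return m.group(1).split("|")


def parse_vep_csq(csq_value: str, csq_format: Sequence[str]) -> list[FunctionalAnnotation]:
    """Parse a VEP CSQ INFO value using the header-declared subfield names.

    ``SYMBOL`` provides the gene name, falling back to ``Gene`` when the
    SYMBOL column is not declared.
    """
    fmt = list(csq_format)
    out: list[FunctionalAnnotation] = []
    for entry in csq_value.split(","):
        parts = entry.split("|")
        if len(parts) != len(fmt):
            raise ParseError(
                f"CSQ entry has {len(parts)} subfields but format declares {len(fmt)}: {entry!r}"
            )
        rec = dict(zip(fmt, parts))
        gene = rec.get("SYMBOL") or rec.get("Gene", "")
        for effect in rec.get("Consequence", "").split("&"):
            if not effect:
                raise ParseError(f"CSQ entry lacks a Consequence: {entry!r}")
            out.append(
                FunctionalAnnotation(
                    allele=rec.get("Allele", ""),
                    effect=effect,
                    impact=rec.get("IMPACT", ""),
                    gene_name=gene,
                )
            )
    return out
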