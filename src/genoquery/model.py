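"""Core domain objects: variants, genotype calls, runs, dataset descriptors.

The data model follows the two-tier layout used by large genotype
warehouses: a small set of indexed, per-variant facts (sequence, position,
type, known alleles) kept separate from the bulky per-individual genotype
"runs" (calls, numeric FORMAT values, functional annotations).  Missing
genotypes are never stored explicitly — absence of an individual's entry in
a run encodes missingness, which keeps sparse datasets compact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

VARIANT_TYPES = ("SNP", "INDEL", "MNP", "OTHER")

_BASES = set("ACGTN*")


def classify_variant_type(known_alleles: Iterable[str]) -> str:
    """Classify a variant from its allele set.

    All alleles length 1 -> SNP; all equal length > 1 -> MNP; differing
    lengths or a ``*`` (spanning deletion) -> INDEL; symbolic alleles
    (``<DEL>``, breakends, ...) -> OTHER.
    """
    alleles = [a.upper() for a in known_alleles]
    if not alleles:
        raise ValueError("variant must have at least one allele")
    for a in alleles:
        if not a or not set(a) <= _BASES:
            return "OTHER"
    if "*" in alleles:
        return "INDEL"
    lengths = {len(a) for a in alleles}
    if lengths == {1}:
        return "SNP"
    if len(lengths) == 1:
        return "MNP"
    return "INDEL"


@dataclass(frozen=True)
class GenotypeCall:
    """A genotype call as a sorted multiset of allele indices.

    Equality ignores phasing and allele order: ``1|0`` and ``0/1`` compare
    equal because both normalise to ``(0, 1)``.  ``phased`` is retained for
    round-tripping only and takes no part in comparisons.
    """

    allele_indices: tuple[int, ...]
    phased: bool = False

    def __post_init__(self):
        object.__setattr__(self, "allele_indices", tuple(sorted(self.allele_indices)))
        if not 1 <= len(self.allele_indices) <= 2:
            raise ValueError(f"call ploidy must be 1 or 2, got {self.allele_indices}")
        if any(i < 0 for i in self.allele_indices):
            raise ValueError("allele indices must be non-negative")

    def __eq__(self, other):
        if not isinstance(other, GenotypeCall):
            return NotImplemented
        return self.allele_indices == other.allele_indices

    def __hash__(self):
        return hash(self.allele_indices)

    @property
    def ploidy(self) -> int:
        return len(self.allele_indices)

    def to_string(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join(str(i) for i in self.allele_indices)

    @classmethod
    def from_string(cls, s: str) -> "GenotypeCall":
        phased = "|" in s
        parts = s.replace("|", "/").split("/")
        return cls(tuple(int(p) for p in parts), phased)


@dataclass(frozen=True)
class VariantRecord:
    """Indexed per-variant facts."""

    variant_id: str
    sequence: str
    position: int  # 1-based
    known_alleles: tuple[str, ...]  # reference first

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.known_alleles:
            raise ValueError("known_alleles must be non-empty")
        object.__setattr__(self, "known_alleles", tuple(self.known_alleles))

    @property
    def variant_type(self) -> str:
        return classify_variant_type(self.known_alleles)

    @property
    def n_alleles(self) -> int:
        return len(self.known_alleles)


@dataclass(frozen=True)
class FunctionalAnnotation:
    """One functional-consequence annotation of a variant allele."""

    allele: str
    effect: str
    impact: str = ""
    gene_name: str = ""

    def __post_init__(self):
        if not self.effect:
            raise ValueError("annotation effect must be non-empty")


@dataclass
class GenotypeRun:
    """Genotype-bearing record for one variant.

    ``calls`` maps individual id -> GenotypeCall; an individual absent from
    the mapping has a missing genotype.  ``numeric_values`` carries the
    per-sample numeric FORMAT values (DP, GQ, ...) that genotype-level
    threshold filters read.
    """

    variant_id: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    numeric_values: dict[str, dict[str, float]] = field(default_factory=dict)
    annotations: list[FunctionalAnnotation] = field(default_factory=list)


@dataclass
class IndividualMetadata:
    individual_id: str
    attributes: dict[str, str] = field(default_factory=dict)


@dataclass
class DatasetDescriptor:
    """Summary of a stored dataset.

    ``numeric_fields`` maps each per-sample numeric FORMAT field detected at
    import to its declared VCF type (``Integer`` or ``Float``); membership
    tests treat it as the set of available field names.
    """

    name: str
    individuals: list[str]
    chunk_size: int = 5000
    ploidy: int = 2
    numeric_fields: dict[str, str] = field(default_factory=dict)
    annotation_source: str = "none"  # none | snpeff | vep
    sequences: list[str] = field(default_factory=list)
    n_variants: int = 0
    chunk_sizes: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        if not self.individuals:
            raise ValueError("dataset needs at least one individual")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual id")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")

    @property
    def n_chunks(self) -> int:
        return len(self.chunk_sizes)


class ValidationError(ValueError):
    """Invalid user input (query, identifiers, structure)."""


class ParseError(ValueError):
    """Malformed input file content."""
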