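"""Query model and genotype-level filter evaluation.

A query combines one variant-level block (type, allele count, sequence,
position, functional annotation) with up to two group-level blocks.  Each
group block selects a subset of individuals and constrains their genotypes
at a variant: a genotype pattern (ANY, or "all or mostly the same" with a
similarity ratio), a MAF interval, a maximum missing-data ratio, and
minimum thresholds on numeric per-sample fields such as DP or GQ.  Ticking
``discriminate`` additionally requires the two groups' major genotypes to
differ — the case/control use, e.g. mapping a sex-determining region by
contrasting males and females.

Conventions (applied consistently everywhere):

* all fraction comparisons are inclusive (missing_ratio <= max passes at
  exactly the bound; major_ratio >= similarity_ratio passes at equality;
  MAF bounds are a closed interval);
* the similarity ratio is taken over *called* genotypes after threshold
  masking — missingness is governed solely by ``max_missing_ratio``;
* genotype equality is unphased (sorted allele multiset);
* MAF is the frequency of the second-most-frequent allele (0 for a
  monomorphic variant, undefined when no genotype is called);
* the major genotype on a tie is the lexicographically smallest normalized
  allele-index multiset, for determinism.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .model import (
    FunctionalAnnotation,
    GenotypeCall,
    GenotypeRun,
    ValidationError,
    VariantRecord,
    VARIANT_TYPES,
)

PATTERN_ANY = "ANY"
PATTERN_SAME = "ALL_OR_MOSTLY_SAME"


@dataclass(frozen=True)
class VariantLevelFilter:
    """Filter on indexed per-variant facts; ``None``/empty means unconstrained."""

    variant_types: Optional[frozenset[str]] = None
    allele_count_min: Optional[int] = None
    allele_count_max: Optional[int] = None
    sequences: Optional[frozenset[str]] = None
    position_min: Optional[int] = None  # 1-based, inclusive
    position_max: Optional[int] = None  # inclusive
    effects: frozenset[str] = frozenset()
    gene_names: frozenset[str] = frozenset()

    def __post_init__(self):
        for f in ("variant_types", "sequences"):
            v = getattr(self, f)
            if v is not None:
                object.__setattr__(self, f, frozenset(v))
        object.__setattr__(self, "effects", frozenset(self.effects))
        object.__setattr__(self, "gene_names", frozenset(self.gene_names))
        if self.variant_types is not None and not self.variant_types <= set(VARIANT_TYPES):
            raise ValidationError(f"unknown variant types: {set(self.variant_types) - set(VARIANT_TYPES)}")
        if (
            self.allele_count_min is not None
            and self.allele_count_max is not None
            and self.allele_count_min > self.allele_count_max
        ):
            raise ValidationError("allele_count_min > allele_count_max")
        if (
            self.position_min is not None
            and self.position_max is not None
            and self.position_min > self.position_max
        ):
            raise ValidationError("position_min > position_max")

    @property
    def needs_annotations(self) -> bool:
        return bool(self.effects or self.gene_names)

    def to_canonical(self) -> dict:
        return {
            "variant_types": sorted(self.variant_types) if self.variant_types is not None else None,
            "allele_count_min": self.allele_count_min,
            "allele_count_max": self.allele_count_max,
            "sequences": sorted(self.sequences) if self.sequences is not None else None,
            "position_min": self.position_min,
            "position_max": self.position_max,
            "effects": sorted(self.effects),
            "gene_names": sorted(self.gene_names),
        }


@dataclass(frozen=True)
class GroupFilter:
    """Genotype-level constraints applied to one group of individuals."""

    individuals: tuple[str, ...]
    pattern: str = PATTERN_ANY
    similarity_ratio: float = 1.0
    maf_min: Optional[float] = None
    maf_max: Optional[float] = None
    max_missing_ratio: Optional[float] = None
    numeric_thresholds: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "individuals", tuple(self.individuals))
        object.__setattr__(self, "numeric_thresholds", dict(self.numeric_thresholds))
        if not self.individuals:
            raise ValidationError("group must contain at least one individual")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValidationError("duplicate individual in group")
        if self.pattern not in (PATTERN_ANY, PATTERN_SAME):
            raise ValidationError(f"unknown pattern {self.pattern!r}")
        if not 0.0 <= self.similarity_ratio <= 1.0:
            raise ValidationError("similarity_ratio must be in [0, 1]")
        for b in (self.maf_min, self.maf_max):
            if b is not None and not 0.0 <= b <= 0.5:
                raise ValidationError("MAF bounds must be in [0, 0.5]")
        if self.maf_min is not None and self.maf_max is not None and self.maf_min > self.maf_max:
            raise ValidationError("maf_min > maf_max")
        if self.max_missing_ratio is not None and not 0.0 <= self.max_missing_ratio <= 1.0:
            raise ValidationError("max_missing_ratio must be in [0, 1]")

    @property
    def has_maf_bounds(self) -> bool:
        return self.maf_min is not None or self.maf_max is not None

    def to_canonical(self) -> dict:
        return {
            "individuals": sorted(self.individuals),
            "pattern": self.pattern,
            "similarity_ratio": self.similarity_ratio if self.pattern == PATTERN_SAME else None,
            "maf_min": self.maf_min,
            "maf_max": self.maf_max,
            "max_missing_ratio": self.max_missing_ratio,
            "numeric_thresholds": {k: self.numeric_thresholds[k] for k in sorted(self.numeric_thresholds)},
        }


@dataclass(frozen=True)
class Query:
    variant_filter: VariantLevelFilter = field(default_factory=VariantLevelFilter)
    group1: Optional[GroupFilter] = None
    group2: Optional[GroupFilter] = None
    discriminate: bool = False

    def __post_init__(self):
        if self.discriminate:
            if self.group1 is None or self.group2 is None:
                raise ValidationError("discriminate requires both groups to be defined")
            if self.group1.pattern != PATTERN_SAME or self.group2.pattern != PATTERN_SAME:
                raise ValidationError(
                    "discriminate requires the ALL_OR_MOSTLY_SAME pattern in both groups"
                )

    @property
    def has_genotype_level(self) -> bool:
        return self.group1 is not None or self.group2 is not None

    def to_canonical(self) -> dict:
        return {
            "variant_filter": self.variant_filter.to_canonical(),
            "group1": self.group1.to_canonical() if self.group1 else None,
            "group2": self.group2.to_canonical() if self.group2 else None,
            "discriminate": self.discriminate,
        }

    def key(self, dataset_id: str) -> str:
        """Stable, field-order-independent cache key for this query."""
        payload = json.dumps({"dataset": dataset_id, "query": self.to_canonical()}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class GroupGenotypeStats:
    """Per-variant per-group tallies the group filters are judged on."""

    n_selected: int
    n_called: int
    missing_ratio: float
    genotype_counts: dict[tuple[int, ...], int]
    major_genotype: Optional[tuple[int, ...]]
    major_ratio: float
    allele_counts: dict[int, int]
    maf: Optional[float]  # None when n_called == 0


def mask_by_thresholds(
    run: GenotypeRun,
    thresholds: Mapping[str, float],
    individuals: Sequence[str],
    known_fields: Optional[set] = None,
) -> dict[str, GenotypeCall]:
    """Return a call view where genotypes failing any threshold are missing.

    A genotype whose value for any thresholded field is absent or below the
    minimum is dropped from the view; stored data is never modified.
    """
    if known_fields is not None:
        unknown = set(thresholds) - set(known_fields)
        if unknown:
            raise ValidationError(
                f"unknown numeric field(s) {sorted(unknown)}; detected fields: {sorted(known_fields)}"
            )
    out: dict[str, GenotypeCall] = {}
    for ind in individuals:
        call = run.calls.get(ind)
        if call is None:
            continue
        if thresholds:
            vals = run.numeric_values.get(ind, {})
            ok = True
            for fname, minimum in thresholds.items():
                v = vals.get(fname)
                if v is None or v < minimum:
                    ok = False
                    break
            if not ok:
                continue
        out[ind] = call
    return out


def group_stats(masked_calls: Mapping[str, GenotypeCall], individuals: Sequence[str]) -> GroupGenotypeStats:
    """Tally genotype and allele counts for one group at one variant."""
    n_selected = len(individuals)
    geno_counts: Counter = Counter()
    allele_counts: Counter = Counter()
    for ind in individuals:
        call = masked_calls.get(ind)
        if call is None:
            continue
        geno_counts[call.allele_indices] += 1
        for a in call.allele_indices:
            allele_counts[a] += 1
    n_called = sum(geno_counts.values())
    missing_ratio = (n_selected - n_called) / n_selected if n_selected else 0.0
    if n_called:
        # modal call; ties broken by the smallest normalized multiset
        major = min(geno_counts, key=lambda g: (-geno_counts[g], g))
        major_ratio = geno_counts[major] / n_called
    else:
        major, major_ratio = None, 0.0
    if allele_counts:
        counts = sorted(allele_counts.values(), reverse=True)
        total = sum(counts)
        maf = counts[1] / total if len(counts) > 1 else 0.0
    else:
        maf = None
    return GroupGenotypeStats(
        n_selected=n_selected,
        n_called=n_called,
        missing_ratio=missing_ratio,
        genotype_counts=dict(geno_counts),
        major_genotype=major,
        major_ratio=major_ratio,
        allele_counts=dict(allele_counts),
        maf=maf,
    )


def evaluate_group_filter(stats: GroupGenotypeStats, gf: GroupFilter):
    """Judge one group's stats against its filter.

    Returns ``(passes, major_genotype)``; the major genotype feeds the
    discrimination test.
    """
    if gf.max_missing_ratio is not None and stats.missing_ratio > gf.max_missing_ratio:
        return False, stats.major_genotype
    if gf.has_maf_bounds:
        if stats.maf is None:
            return False, stats.major_genotype
        lo = gf.maf_min if gf.maf_min is not None else 0.0
        hi = gf.maf_max if gf.maf_max is not None else 0.5
        if not lo <= stats.maf <= hi:
            return False, stats.major_genotype
    if gf.pattern == PATTERN_SAME:
        if stats.n_called == 0 or stats.major_ratio < gf.similarity_ratio:
            return False, stats.major_genotype
    return True, stats.major_genotype


def evaluate_discrimination(result1, result2) -> bool:
    """True iff both groups pass and their (defined) major genotypes differ."""
    pass1, major1 = result1
    pass2, major2 = result2
    return bool(pass1 and pass2 and major1 is not None and major2 is not None and major1 != major2)


def evaluate_variant_level(
    record: VariantRecord,
    annotations: Sequence[FunctionalAnnotation],
    vf: VariantLevelFilter,
) -> bool:
    """Conjunction of the indexed per-variant conditions."""
    if vf.variant_types is not None and record.variant_type not in vf.variant_types:
        return False
    if vf.allele_count_min is not None and record.n_alleles < vf.allele_count_min:
        return False
    if vf.allele_count_max is not None and record.n_alleles > vf.allele_count_max:
        return False
    if vf.sequences is not None and record.sequence not in vf.sequences:
        return False
    if vf.position_min is not None and record.position < vf.position_min:
        return False
    if vf.position_max is not None and record.position > vf.position_max:
        return False
    if vf.effects and not any(a.effect in vf.effects for a in annotations):
        return False
    if vf.gene_names and not any(a.gene_name in vf.gene_names for a in annotations):
        return False
    return True


def evaluate_variant_level_indexed(
    record: VariantRecord,
    effects: Sequence[str],
    genes: Sequence[str],
    vf: VariantLevelFilter,
) -> bool:
    """Variant-level test against index rows (precomputed effect/gene lists)."""
    if vf.variant_types is not None and record.variant_type not in vf.variant_types:
        return False
    if vf.allele_count_min is not None and record.n_alleles < vf.allele_count_min:
        return False
    if vf.allele_count_max is not None and record.n_alleles > vf.allele_count_max:
        return False
    if vf.sequences is not None and record.sequence not in vf.sequences:
        return False
    if vf.position_min is not None and record.position < vf.position_min:
        return False
    if vf.position_max is not None and record.position > vf.position_max:
        return False
    if vf.effects and not (vf.effects & set(effects)):
        return False
    if vf.gene_names and not (vf.gene_names & set(genes)):
        return False
    return True


def evaluate_query_on_variant(
    record: VariantRecord,
    run: GenotypeRun,
    query: Query,
    known_fields: Optional[set] = None,
) -> bool:
    """Full per-variant decision: variant-level test, then group logic."""
    if not evaluate_variant_level(record, run.annotations, query.variant_filter):
        return False
    if not query.has_genotype_level:
        return True
    results = []
    for gf in (query.group1, query.group2):
        if gf is None:
            continue
        masked = mask_by_thresholds(run, gf.numeric_thresholds, gf.individuals, known_fields)
        stats = group_stats(masked, gf.individuals)
        results.append(evaluate_group_filter(stats, gf))
    if query.discriminate:
        return evaluate_discrimination(results[0], results[1])
    return all(passed for passed, _ in results)
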