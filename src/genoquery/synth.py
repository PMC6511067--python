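"""Deterministic synthetic multi-sample VCF generator.

Emulates the statistical structure the filter engine reads — per-variant
allele frequencies, per-call missingness, per-sample DP/GQ values,
SnpEff-style ANN annotations — without population-genetic realism (no
linkage, no coalescent structure).  Optionally "plants" variants whose
genotypes discriminate two predefined groups of individuals: each group
member receives its group's signature genotype with probability ``purity``,
and planted calls of group members are never masked as missing, so a purity
1.0 plant is guaranteed to pass a discrimination query at similarity ratio
1.0 and missing-data maximum 0.

Generation is a pure function of the spec: the same seed yields
byte-identical output.  Alongside the VCF, a truth table records the
realized per-variant tallies (computed from the emitted genotypes, not the
sampling law).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import GenotypeCall, ValidationError

_EFFECTS = [
    ("missense_variant", "MODERATE"),
    ("synonymous_variant", "LOW"),
    ("intron_variant", "MODIFIER"),
    ("stop_gained", "HIGH"),
    ("upstream_gene_variant", "MODIFIER"),
]
_BASES = "ACGT"


@dataclass(frozen=True)
class PlantedVariant:
    """A variant constructed to discriminate two disjoint individual groups."""

    sequence: str
    position: int
    group1_ids: tuple[str, ...]
    group2_ids: tuple[str, ...]
    signature1: str = "0/0"
    signature2: str = "1/1"
    purity1: float = 1.0
    purity2: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "group1_ids", tuple(self.group1_ids))
        object.__setattr__(self, "group2_ids", tuple(self.group2_ids))
        if set(self.group1_ids) & set(self.group2_ids):
            raise ValidationError("planted groups must be disjoint")
        if GenotypeCall.from_string(self.signature1) == GenotypeCall.from_string(self.signature2):
            raise ValidationError("signature genotypes must differ (unphased comparison)")


@dataclass
class SynthSpec:
    """Generator conditions; all randomness derives from ``seed``."""

    n_individuals: int = 50
    n_variants: int = 1000  # neutral variants; planted ones are added on top
    sequences: tuple = (("chr1", 1_000_000),)
    maf_low: float = 0.05  # alt-allele frequency drawn uniformly per variant
    maf_high: float = 0.5
    missing_rate: float = 0.05
    dp_range: tuple = (5, 60)
    gq_range: tuple = (20, 99)
    annotation_rate: float = 0.2
    indel_rate: float = 0.0
    planted: tuple = ()
    seed: int = 0

    def __post_init__(self):
        for r in (self.missing_rate, self.annotation_rate, self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValidationError("rates must be in [0, 1]")
        lengths = dict(self.sequences)
        for p in self.planted:
            if p.sequence not in lengths or not 1 <= p.position <= lengths[p.sequence]:
                raise ValidationError(
                    f"planted position {p.sequence}:{p.position} outside declared sequences"
                )

    @property
    def individuals(self) -> list[str]:
        return [f"ind{i:04d}" for i in range(self.n_individuals)]


@dataclass
class GenerateResult:
    vcf_path: str
    individuals: list[str]
    truth: list[dict]  # per-variant realized tallies, VCF order
    planted_ids: list[str] = field(default_factory=list)
    truth_path: Optional[str] = None
    metadata_path: Optional[str] = None


def _draw_positions(rng, length: int, k: int, exclude: set) -> list[int]:
    """k distinct 1-based positions, avoiding huge permutation buffers."""
    chosen: set = set()
    while len(chosen) < k:
        need = (k - len(chosen)) * 2 + 10
        for p in rng.integers(1, length + 1, size=need):
            p = int(p)
            if p not in exclude and p not in chosen:
                chosen.add(p)
                if len(chosen) == k:
                    break
    return sorted(chosen)


def generate(
    spec: SynthSpec,
    out_vcf,
    truth_path=None,
    metadata_path=None,
) -> GenerateResult:
    """Write the synthetic VCF (+ optional truth table and metadata TSV)."""
    rng = np.random.default_rng(spec.seed)
    inds = spec.individuals
    ind_pos = {ind: i for i, ind in enumerate(inds)}
    seq_names = [s for s, _l in spec.sequences]

    # layout: neutral variants spread over sequences, then merge planted
    planted_by_site = {(p.sequence, p.position): p for p in spec.planted}
    per_seq = {s: [] for s in seq_names}
    seq_choice = rng.integers(0, len(seq_names), size=spec.n_variants)
    counts = Counter(seq_names[i] for i in seq_choice)
    for s, length in spec.sequences:
        excl = {pos for (sq, pos) in planted_by_site if sq == s}
        per_seq[s] = _draw_positions(rng, length, counts.get(s, 0), excl)
    sites = []
    for s, _l in spec.sequences:
        allpos = sorted(per_seq[s] + [pos for (sq, pos) in planted_by_site if sq == s])
        sites.extend((s, p) for p in allpos)

    dp_lo, dp_hi = spec.dp_range
    gq_lo, gq_hi = spec.gq_range
    truth: list[dict] = []
    planted_ids: list[str] = []
    lines: list[str] = []
    header = ["##fileformat=VCFv4.2", "##source=genoquery-synth"]
    for s, length in spec.sequences:
        header.append(f"##contig=<ID={s},length={length}>")
    header += [
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations:'
        " 'Allele | Annotation | Annotation_Impact | Gene_Name'\">",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(inds),
    ]

    for vi, (seq, pos) in enumerate(sites):
        vid = f"sv{vi:06d}"
        plant = planted_by_site.get((seq, pos))
        ref = _BASES[rng.integers(4)]
        alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
        if plant is None and rng.random() < spec.indel_rate:
            alt = ref + _BASES[rng.integers(4)]
        p_alt = rng.uniform(spec.maf_low, spec.maf_high)

        gts: list[Optional[tuple[int, int]]] = []
        draws = rng.random((len(inds), 3))  # two allele draws + missing draw
        for ind in inds:
            a = draws[ind_pos[ind]]
            gt = (int(a[0] < p_alt), int(a[1] < p_alt))
            if a[2] < spec.missing_rate:
                gt = None
            gts.append(tuple(sorted(gt)) if gt else None)
        if plant is not None:
            for ids, sig, purity in (
                (plant.group1_ids, plant.signature1, plant.purity1),
                (plant.group2_ids, plant.signature2, plant.purity2),
            ):
                sig_call = tuple(GenotypeCall.from_string(sig).allele_indices)
                for ind in ids:
                    i = ind_pos[ind]
                    if rng.random() < purity:
                        gts[i] = sig_call  # planted member calls are never missing
                    elif gts[i] is None:
                        gts[i] = (int(draws[i][0] < p_alt), int(draws[i][1] < p_alt))
            planted_ids.append(vid)

        dps = rng.integers(dp_lo, dp_hi + 1, size=len(inds))
        gqs = rng.integers(gq_lo, gq_hi + 1, size=len(inds))
        ann_draw = rng.random()
        info = "."
        if ann_draw < spec.annotation_rate:
            effect, impact = _EFFECTS[rng.integers(len(_EFFECTS))]
            gene = f"GENE{int(rng.integers(10))}"
            info = f"ANN={alt}|{effect}|{impact}|{gene}|extra"

        cols = []
        allele_counts: Counter = Counter()
        n_called = 0
        for i, ind in enumerate(inds):
            gt = gts[i]
            g = "./." if gt is None else f"{gt[0]}/{gt[1]}"
            if gt is not None:
                n_called += 1
                allele_counts.update(gt)
            cols.append(f"{g}:{dps[i]}:{gqs[i]}")
        lines.append(
            f"{seq}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t{info}\tGT:DP:GQ\t" + "\t".join(cols)
        )
        total_alleles = sum(allele_counts.values())
        if total_alleles:
            sorted_counts = sorted(allele_counts.values(), reverse=True)
            maf = sorted_counts[1] / total_alleles if len(sorted_counts) > 1 else 0.0
        else:
            maf = None
        truth.append(
            {
                "variant_id": vid,
                "sequence": seq,
                "position": pos,
                "n_called": n_called,
                "n_missing": len(inds) - n_called,
                "alt_allele_count": allele_counts.get(1, 0),
                "maf": maf,
                "planted": plant is not None,
            }
        )

    Path(out_vcf).write_text("\n".join(header + lines) + "\n")

    if truth_path:
        cols = ["variant_id", "sequence", "position", "n_called", "n_missing",
                "alt_allele_count", "maf", "planted"]
        rows = ["\t".join(cols)]
        for t in truth:
            rows.append("\t".join("" if t[c] is None else str(t[c]) for c in cols))
        Path(truth_path).write_text("\n".join(rows) + "\n")

    if metadata_path:
        g1 = set().union(*(set(p.group1_ids) for p in spec.planted)) if spec.planted else set()
        g2 = set().union(*(set(p.group2_ids) for p in spec.planted)) if spec.planted else set()
        rows = ["individual\tgroup"]
        for ind in inds:
            grp = "group1" if ind in g1 else "group2" if ind in g2 else ""
            rows.append(f"{ind}\t{grp}")
        Path(metadata_path).write_text("\n".join(rows) + "\n")

    return GenerateResult(
        vcf_path=str(out_vcf),
        individuals=inds,
        truth=truth,
        planted_ids=planted_ids,
        truth_path=str(truth_path) if truth_path else None,
        metadata_path=str(metadata_path) if metadata_path else None,
    )


@dataclass
class RecoveryReport:
    result_ids: list[str]
    recovered: list[str]  # planted variants found by the query
    missed: list[str]  # planted variants the query did not return
    extra: list[str]  # non-planted variants the query returned


def plant_recovery_check(
    store,
    dataset,
    gen: GenerateResult,
    spec: SynthSpec,
    similarity_ratio: float = 1.0,
    max_missing_ratio: float = 0.0,
    workers: Optional[int] = None,
) -> RecoveryReport:
    """Run the discrimination query over generated data and compare to plants."""
    from .engine import execute_query
    from .filters import GroupFilter, Query, PATTERN_SAME

    if not spec.planted:
        raise ValidationError("spec has no planted variants")
    g1 = spec.planted[0].group1_ids
    g2 = spec.planted[0].group2_ids
    query = Query(
        group1=GroupFilter(g1, PATTERN_SAME, similarity_ratio, max_missing_ratio=max_missing_ratio),
        group2=GroupFilter(g2, PATTERN_SAME, similarity_ratio, max_missing_ratio=max_missing_ratio),
        discriminate=True,
    )
    res = execute_query(store, dataset, query, mode="find", workers=workers)
    found = set(res.variant_ids)
    planted = set(gen.planted_ids)
    return RecoveryReport(
        result_ids=res.variant_ids,
        recovered=sorted(planted & found),
        missed=sorted(planted - found),
        extra=sorted(found - planted),
    )
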