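"""Plain-text query file format.

One ``key = value`` pair per line; ``#`` starts a comment.  Variant-level
keys: ``types``, ``min-alleles``, ``max-alleles``, ``seqs``, ``start``,
``end``, ``effects``, ``genes`` (lists are comma-separated).  Group keys are
prefixed ``group1.`` / ``group2.``: ``individuals`` (comma list, or
``@path`` naming a file with one id per line), ``pattern`` (ANY or
ALL_OR_MOSTLY_SAME), ``ratio``, ``maf-min``, ``maf-max``, ``max-missing``,
and ``min.FIELD = value`` for numeric thresholds.  ``discriminate = true``
turns on group discrimination.

Example::

    seqs = chr10
    group1.individuals = @males.txt
    group1.pattern = ALL_OR_MOSTLY_SAME
    group1.ratio = 0.90
    group1.max-missing = 0.10
    group1.min.DP = 5
    group2.individuals = @females.txt
    group2.pattern = ALL_OR_MOSTLY_SAME
    group2.ratio = 0.90
    group2.max-missing = 0.10
    discriminate = true

The canonical form used for cache keys is the sorted-key JSON of
``Query.to_canonical()``; two files spelling the same query in different
orders hash identically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .filters import GroupFilter, Query, VariantLevelFilter
from .model import ValidationError

_VARIANT_KEYS = {"types", "min-alleles", "max-alleles", "seqs", "start", "end", "effects", "genes"}
_GROUP_KEYS = {"individuals", "pattern", "ratio", "maf-min", "maf-max", "max-missing"}


def _read_id_list(value: str, base_dir: Path) -> tuple[str, ...]:
    if value.startswith("@"):
        path = base_dir / value[1:]
        return tuple(
            line.strip() for line in path.read_text().splitlines() if line.strip()
        )
    return tuple(v.strip() for v in value.split(",") if v.strip())


def parse_query_text(text: str, base_dir: Path = Path(".")) -> Query:
    kv: dict[str, str] = {}
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"query file line {ln}: expected 'key = value': {raw!r}")
        k, v = line.split("=", 1)
        kv[k.strip()] = v.strip()

    def pop_list(key):
        v = kv.pop(key, None)
        return frozenset(x.strip() for x in v.split(",") if x.strip()) if v else None

    vf = VariantLevelFilter(
        variant_types=pop_list("types"),
        allele_count_min=int(kv.pop("min-alleles")) if "min-alleles" in kv else None,
        allele_count_max=int(kv.pop("max-alleles")) if "max-alleles" in kv else None,
        sequences=pop_list("seqs"),
        position_min=int(kv.pop("start")) if "start" in kv else None,
        position_max=int(kv.pop("end")) if "end" in kv else None,
        effects=pop_list("effects") or frozenset(),
        gene_names=pop_list("genes") or frozenset(),
    )
    discriminate = kv.pop("discriminate", "false").lower() in ("true", "1", "yes")

    groups: dict[str, Optional[GroupFilter]] = {}
    for g in ("group1", "group2"):
        gkv = {k[len(g) + 1 :]: kv.pop(k) for k in list(kv) if k.startswith(g + ".")}
        if not gkv:
            groups[g] = None
            continue
        thresholds = {}
        for k in list(gkv):
            if k.startswith("min."):
                thresholds[k[4:]] = float(gkv.pop(k))
        unknown = set(gkv) - _GROUP_KEYS
        if unknown:
            raise ValidationError(f"unknown query key(s): {sorted(g + '.' + u for u in unknown)}")
        if "individuals" not in gkv:
            raise ValidationError(f"{g}: 'individuals' is required")
        groups[g] = GroupFilter(
            individuals=_read_id_list(gkv["individuals"], base_dir),
            pattern=gkv.get("pattern", "ANY"),
            similarity_ratio=float(gkv.get("ratio", 1.0)),
            maf_min=float(gkv["maf-min"]) if "maf-min" in gkv else None,
            maf_max=float(gkv["maf-max"]) if "maf-max" in gkv else None,
            max_missing_ratio=float(gkv["max-missing"]) if "max-missing" in gkv else None,
            numeric_thresholds=thresholds,
        )
    if kv:
        raise ValidationError(f"unknown query key(s): {sorted(kv)}")
    return Query(vf, groups["group1"], groups["group2"], discriminate)


def parse_query_file(path) -> Query:
    p = Path(path)
    return parse_query_text(p.read_text(), base_dir=p.parent)
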