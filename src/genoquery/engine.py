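"""Chunked query execution with per-chunk count caching.

A query is evaluated chunk by chunk: the variant-level test runs first
against the indexed facts, and the genotype runs of a chunk are only loaded
when the query carries group-level filters — a variant-level-only query
never touches the chunk blobs.  Chunks may be evaluated concurrently by a
bounded worker pool; the result is independent of scheduling because chunks
share no state and results are reassembled in chunk order.

Count results are cached per chunk under a canonical query key; a later
``count`` of the same query answers from the cache, and a later ``find``
uses the cached per-chunk counts to stop scanning each chunk as soon as its
known number of matches has been emitted.
"""

from __future__ import annotations

import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Callable, Optional

from .filters import (
    Query,
    evaluate_discrimination,
    evaluate_group_filter,
    evaluate_variant_level_indexed,
    group_stats,
    mask_by_thresholds,
)
from .model import DatasetDescriptor, ValidationError
from .store import VariantStore

ProgressCallback = Callable[[int, int], None]


@dataclass
class QueryResult:
    total_count: int
    per_chunk_counts: list[int]
    variant_ids: Optional[list[str]]  # find mode only; dataset import order
    from_cache: bool = False


def validate_query(dataset: DatasetDescriptor, query: Query) -> None:
    """Reject queries that do not resolve against the dataset, before any work."""
    known = set(dataset.individuals)
    for label, gf in (("group1", query.group1), ("group2", query.group2)):
        if gf is None:
            continue
        bad = set(gf.individuals) - known
        if bad:
            raise ValidationError(f"{label}: unknown individual(s) {sorted(bad)[:5]}")
        unknown = set(gf.numeric_thresholds) - set(dataset.numeric_fields)
        if unknown:
            raise ValidationError(
                f"{label}: unknown numeric field(s) {sorted(unknown)};"
                f" detected fields: {sorted(dataset.numeric_fields)}"
            )


def _evaluate_chunk(
    store: VariantStore,
    dataset: DatasetDescriptor,
    query: Query,
    chunk: int,
    limit: Optional[int] = None,
) -> list[str]:
    """Matching variant ids of one chunk, in import order.

    ``limit`` enables early stop when the chunk's match count is already
    known from the cache.
    """
    if limit == 0:
        return []
    rows = store.chunk_variant_rows(dataset, chunk)
    vf = query.variant_filter
    need_runs = query.has_genotype_level
    runs = store.load_chunk_runs(dataset, chunk) if need_runs else None
    fields = set(dataset.numeric_fields)
    matches: list[str] = []
    for i, (idx, rec, effects, genes) in enumerate(rows):
        if not evaluate_variant_level_indexed(rec, effects, genes, vf):
            continue
        if need_runs:
            run = runs[i]
            results = []
            for gf in (query.group1, query.group2):
                if gf is None:
                    continue
                masked = mask_by_thresholds(run, gf.numeric_thresholds, gf.individuals, fields)
                results.append(evaluate_group_filter(group_stats(masked, gf.individuals), gf))
            if query.discriminate:
                if not evaluate_discrimination(results[0], results[1]):
                    continue
            elif not all(passed for passed, _ in results):
                continue
        matches.append(rec.variant_id)
        if limit is not None and len(matches) == limit:
            break
    return matches


def execute_query(
    store: VariantStore,
    dataset: DatasetDescriptor,
    query: Query,
    mode: str = "count",
    count_at_same_time: bool = False,
    progress: Optional[ProgressCallback] = None,
    workers: Optional[int] = None,
) -> QueryResult:
    """Run a query over all chunks of a dataset.

    ``mode="count"`` returns the total only; ``mode="find"`` also returns
    the ordered matching variant ids (and, in a single pass, the per-chunk
    counts — the "count at the same time" behaviour, so a separate count
    query is never needed).
    """
    if mode not in ("count", "find"):
        raise ValidationError(f"unknown mode {mode!r}")
    validate_query(dataset, query)
    cache = store.cache(dataset)
    key = query.key(dataset.name)
    cached = cache.get(key)

    if mode == "count" and cached is not None:
        if progress:
            progress(dataset.n_chunks, dataset.n_chunks)
        return QueryResult(sum(cached), cached, None, from_cache=True)

    n_chunks = dataset.n_chunks
    done = 0

    def eval_one(chunk: int) -> list[str]:
        limit = cached[chunk] if cached is not None else None
        return _evaluate_chunk(store, dataset, query, chunk, limit=limit)

    if n_chunks == 0:
        per_chunk: list[list[str]] = []
    elif workers == 1 or n_chunks == 1:
        per_chunk = []
        for c in range(n_chunks):
            per_chunk.append(eval_one(c))
            done += 1
            if progress:
                progress(done, n_chunks)
    else:
        max_workers = workers or os.cpu_count() or 1
        with ThreadPoolExecutor(max_workers=max_workers) as pool:
            futures = [pool.submit(eval_one, c) for c in range(n_chunks)]
            per_chunk = []
            for f in futures:
                per_chunk.append(f.result())
                done += 1
                if progress:
                    progress(done, n_chunks)

    counts = [len(m) for m in per_chunk]
    cache.put(key, counts)
    ids = [vid for m in per_chunk for vid in m] if mode == "find" else None
    return QueryResult(sum(counts), counts, ids, from_cache=cached is not None)
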