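"""Persistent chunked variant store.

Layout: one directory per dataset under the store root.

* ``descriptor.json`` — dataset summary (individuals, chunk sizes, detected
  numeric fields, annotation source);
* ``variants.db`` — sqlite3 index of per-variant facts (sequence, position,
  type, allele count, annotation effect/gene lists), one row per variant in
  import order;
* ``chunks/chunk_NNNNN.json.gz`` — genotype runs for one chunk of variants,
  in import order; missing genotypes are simply absent from the mapping;
* ``cache.json`` — per-query arrays of per-chunk match counts.

Variants are chunked by import order into blocks of ``chunk_size`` (default
5000).  Incremental ingest appends new chunks and never rewrites existing
ones, so the final chunk of an earlier ingest may stay short.  Any ingest
invalidates the dataset's count cache.
"""

from __future__ import annotations

import gzip
import json
import sqlite3
import threading
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .model import (
    DatasetDescriptor,
    FunctionalAnnotation,
    GenotypeCall,
    GenotypeRun,
    ValidationError,
    VariantRecord,
)

DESCRIPTOR = "descriptor.json"
VARIANT_DB = "variants.db"
CACHE_FILE = "cache.json"
CHUNK_DIR = "chunks"

_SCHEMA = """
CREATE TABLE IF NOT EXISTS variants (
    idx INTEGER PRIMARY KEY,
    variant_id TEXT UNIQUE NOT NULL,
    sequence TEXT NOT NULL,
    position INTEGER NOT NULL,
    variant_type TEXT NOT NULL,
    n_alleles INTEGER NOT NULL,
    alleles TEXT NOT NULL,
    chunk INTEGER NOT NULL,
    effects TEXT NOT NULL DEFAULT '[]',
    genes TEXT NOT NULL DEFAULT '[]'
);
CREATE INDEX IF NOT EXISTS ix_seq_pos ON variants (sequence, position);
CREATE INDEX IF NOT EXISTS ix_type ON variants (variant_type);
CREATE INDEX IF NOT EXISTS ix_nall ON variants (n_alleles);
CREATE INDEX IF NOT EXISTS ix_chunk ON variants (chunk);
"""


class AlreadyExistsError(ValueError):
    pass


class ChunkCountCache:
    """Per-query cached arrays of per-chunk match counts.

    The sum of a cached array equals the query's total result count; an
    array always has one entry per chunk of the dataset.
    """

    def __init__(self, path: Path, n_chunks: int):
        self._path = path
        self._n_chunks = n_chunks
        self._lock = threading.Lock()

    def _load(self) -> dict:
        if self._path.exists():
            return json.loads(self._path.read_text())
        return {}

    def get(self, query_key: str) -> Optional[list[int]]:
        entry = self._load().get(query_key)
        return list(entry) if entry is not None else None

    def put(self, query_key: str, counts: list[int]) -> None:
        counts = [int(c) for c in counts]
        if len(counts) != self._n_chunks:
            raise ValidationError(
                f"count array length {len(counts)} != chunk count {self._n_chunks}"
            )
        if any(c < 0 for c in counts):
            raise ValidationError("counts must be non-negative")
        with self._lock:
            entries = self._load()
            entries[query_key] = counts
            self._path.write_text(json.dumps(entries))

    def clear(self) -> None:
        if self._path.exists():
            self._path.unlink()


def _run_to_json(run: GenotypeRun) -> dict:
    d: dict = {"v": run.variant_id}
    if run.calls:
        d["c"] = {ind: call.to_string() for ind, call in run.calls.items()}
    if run.numeric_values:
        d["n"] = run.numeric_values
    if run.annotations:
        d["a"] = [[a.allele, a.effect, a.impact, a.gene_name] for a in run.annotations]
    return d


def _run_from_json(d: dict) -> GenotypeRun:
    return GenotypeRun(
        variant_id=d["v"],
        calls={ind: GenotypeCall.from_string(s) for ind, s in d.get("c", {}).items()},
        numeric_values=d.get("n", {}),
        annotations=[FunctionalAnnotation(*a) for a in d.get("a", [])],
    )


class IngestSummary:
    def __init__(self, variants_added: int, chunks_created: int):
        self.variants_added = variants_added
        self.chunks_created = chunks_created

    def __repr__(self):
        return f"IngestSummary(variants_added={self.variants_added}, chunks_created={self.chunks_created})"


class VariantStore:
    """Directory-per-dataset store rooted at ``root``."""

    def __init__(self, root):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    # -- dataset lifecycle -------------------------------------------------

    def _dir(self, name: str) -> Path:
        return self.root / name

    def list_datasets(self) -> list[str]:
        return sorted(p.name for p in self.root.iterdir() if (p / DESCRIPTOR).exists())

    def create_dataset(
        self, name: str, individuals: list[str], chunk_size: int = 5000, ploidy: int = 2
    ) -> DatasetDescriptor:
        d = self._dir(name)
        if (d / DESCRIPTOR).exists():
            raise AlreadyExistsError(f"dataset {name!r} already exists")
        desc = DatasetDescriptor(
            name=name, individuals=list(individuals), chunk_size=chunk_size, ploidy=ploidy
        )
        d.mkdir(parents=True, exist_ok=True)
        (d / CHUNK_DIR).mkdir(exist_ok=True)
        with self._db(name) as con:
            con.executescript(_SCHEMA)
        self._write_descriptor(desc)
        return desc

    def open_dataset(self, name: str) -> DatasetDescriptor:
        p = self._dir(name) / DESCRIPTOR
        if not p.exists():
            raise ValidationError(f"no dataset named {name!r} in store {self.root}")
        return DatasetDescriptor(**json.loads(p.read_text()))

    def _write_descriptor(self, desc: DatasetDescriptor) -> None:
        payload = {
            "name": desc.name,
            "individuals": desc.individuals,
            "chunk_size": desc.chunk_size,
            "ploidy": desc.ploidy,
            "numeric_fields": desc.numeric_fields,
            "annotation_source": desc.annotation_source,
            "sequences": desc.sequences,
            "n_variants": desc.n_variants,
            "chunk_sizes": desc.chunk_sizes,
        }
        (self._dir(desc.name) / DESCRIPTOR).write_text(json.dumps(payload, indent=1))

    def _db(self, name: str) -> sqlite3.Connection:
        return sqlite3.connect(self._dir(name) / VARIANT_DB)

    # -- ingest ------------------------------------------------------------

    def ingest(
        self,
        dataset: DatasetDescriptor,
        records: Iterable[tuple[VariantRecord, GenotypeRun]],
        numeric_fields: Optional[dict] = None,
        annotation_source: Optional[str] = None,
    ) -> IngestSummary:
        """Append a stream of (variant, run) pairs as new chunks.

        Raises on variant-id collision or on a run referencing an individual
        not in the dataset.  Clears the dataset's count cache.
        """
        known = set(dataset.individuals)
        chunk_idx = dataset.n_chunks
        buffer: list[dict] = []
        added = 0
        chunks_created = 0
        fields = dict(dataset.numeric_fields)
        if numeric_fields:
            fields.update(numeric_fields)
        seqs = list(dataset.sequences)
        seq_seen = set(seqs)

        def flush(con):
            nonlocal chunk_idx, chunks_created
            if not buffer:
                return
            path = self._dir(dataset.name) / CHUNK_DIR / f"chunk_{chunk_idx:05d}.json.gz"
            with gzip.open(path, "wt") as fh:
                json.dump(buffer, fh)
            dataset.chunk_sizes.append(len(buffer))
            chunk_idx += 1
            chunks_created += 1
            buffer.clear()

        with self._db(dataset.name) as con:
            for record, run in records:
                if record.variant_id != run.variant_id:
                    raise ValidationError(
                        f"record/run id mismatch: {record.variant_id} vs {run.variant_id}"
                    )
                bad = (set(run.calls) | set(run.numeric_values)) - known
                if bad:
                    raise ValidationError(f"unknown individual id(s): {sorted(bad)}")
                for ind, vals in run.numeric_values.items():
                    for fname, v in vals.items():
                        if fname not in fields:
                            fields[fname] = "Integer" if float(v).is_integer() else "Float"
                        elif fields[fname] == "Integer" and not float(v).is_integer():
                            fields[fname] = "Float"
                if record.sequence not in seq_seen:
                    seq_seen.add(record.sequence)
                    seqs.append(record.sequence)
                try:
                    con.execute(
                        "INSERT INTO variants (variant_id, sequence, position, variant_type,"
                        " n_alleles, alleles, chunk, effects, genes) VALUES (?,?,?,?,?,?,?,?,?)",
                        (
                            record.variant_id,
                            record.sequence,
                            record.position,
                            record.variant_type,
                            record.n_alleles,
                            json.dumps(list(record.known_alleles)),
                            chunk_idx,
                            json.dumps(sorted({a.effect for a in run.annotations})),
                            json.dumps(sorted({a.gene_name for a in run.annotations if a.gene_name})),
                        ),
                    )
                except sqlite3.IntegrityError as e:
                    raise ValidationError(f"variant id collision: {record.variant_id}") from e
                buffer.append(_run_to_json(run))
                added += 1
                if len(buffer) == dataset.chunk_size:
                    flush(con)
            flush(con)

        dataset.n_variants += added
        dataset.numeric_fields = fields
        dataset.sequences = seqs
        if annotation_source and annotation_source != "none":
            dataset.annotation_source = annotation_source
        self._write_descriptor(dataset)
        self.cache(dataset).clear()  # counts are stale after any data change
        return IngestSummary(added, chunks_created)

    # -- retrieval ---------------------------------------------------------

    def chunk_variant_rows(self, dataset: DatasetDescriptor, chunk: int) -> list[tuple]:
        """Rows ``(idx, VariantRecord, effects, genes)`` for one chunk, import order."""
        with self._db(dataset.name) as con:
            rows = con.execute(
                "SELECT idx, variant_id, sequence, position, alleles, effects, genes"
                " FROM variants WHERE chunk = ? ORDER BY idx",
                (chunk,),
            ).fetchall()
        out = []
        for idx, vid, seq, pos, alleles, effects, genes in rows:
            rec = VariantRecord(vid, seq, pos, tuple(json.loads(alleles)))
            out.append((idx, rec, json.loads(effects), json.loads(genes)))
        return out

    def load_chunk_runs(self, dataset: DatasetDescriptor, chunk: int) -> list[GenotypeRun]:
        path = self._dir(dataset.name) / CHUNK_DIR / f"chunk_{chunk:05d}.json.gz"
        with gzip.open(path, "rt") as fh:
            return [_run_from_json(d) for d in json.load(fh)]

    def iter_records(
        self, dataset: DatasetDescriptor, variant_ids: Optional[set] = None
    ) -> Iterator[tuple[VariantRecord, GenotypeRun]]:
        """All (variant, run) pairs in import order, optionally id-filtered."""
        for chunk in range(dataset.n_chunks):
            rows = self.chunk_variant_rows(dataset, chunk)
            runs = self.load_chunk_runs(dataset, chunk)
            for (idx, rec, _eff, _gen), run in zip(rows, runs):
                if variant_ids is not None and rec.variant_id not in variant_ids:
                    continue
                yield rec, run

    def get_record(self, dataset: DatasetDescriptor, variant_id: str):
        with self._db(dataset.name) as con:
            row = con.execute(
                "SELECT idx, sequence, position, alleles, chunk FROM variants WHERE variant_id = ?",
                (variant_id,),
            ).fetchone()
        if row is None:
            raise ValidationError(f"unknown variant {variant_id!r}")
        idx, seq, pos, alleles, chunk = row
        return VariantRecord(variant_id, seq, pos, tuple(json.loads(alleles))), chunk

    def variant_positions(
        self,
        dataset: DatasetDescriptor,
        sequence: str,
        position_min: int,
        position_max: int,
        variant_ids: Optional[set] = None,
    ) -> list[int]:
        """Positions (import order) of variants on a sequence interval."""
        with self._db(dataset.name) as con:
            rows = con.execute(
                "SELECT variant_id, position FROM variants"
                " WHERE sequence = ? AND position BETWEEN ? AND ? ORDER BY idx",
                (sequence, position_min, position_max),
            ).fetchall()
        return [pos for vid, pos in rows if variant_ids is None or vid in variant_ids]

    # -- cache -------------------------------------------------------------

    def cache(self, dataset: DatasetDescriptor) -> ChunkCountCache:
        return ChunkCountCache(self._dir(dataset.name) / CACHE_FILE, dataset.n_chunks)
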