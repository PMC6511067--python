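"""Export a query's result set (or a whole dataset) to standard formats.

The individual subset chosen at export time is independent of any group
used for filtering.  Records are written in dataset import order.  Reading
and writing are decoupled: a reader thread pulls chunks from the store into
a bounded buffer while the writer drains earlier chunks to the output, so
slow output never blocks chunk loading and vice versa.

Formats
-------
vcf
    Full fidelity: genotypes (with phasing), numeric FORMAT fields, and
    functional annotations are regenerated.  ``.gz`` paths gzip the output.
plink
    ``<out>.ped`` + ``<out>.map``; missing written as ``0 0``; phasing and
    numeric fields are not representable.
hapmap
    SNPs only — variants with non-single-letter alleles are skipped and
    counted; missing written as ``NN``.
flapjack
    A ``.fjzip`` zip archive holding Flapjack's flat genotype matrix
    (``genotypes.txt``, header ``# fjFile = GENOTYPE``, rows = individuals)
    and map (``map.txt``, ``# fjFile = MAP``).
"""

from __future__ import annotations

import gzip
import queue
import threading
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

from .io.hapmap import HAPMAP_COLUMNS
from .model import DatasetDescriptor, GenotypeRun, ValidationError, VariantRecord
from .store import VariantStore

_SENTINEL = None
_BUFFER_CHUNKS = 4

FORMATS = ("vcf", "plink", "hapmap", "flapjack")


@dataclass
class ExportSummary:
    n_variants: int
    n_individuals: int
    skipped: int = 0  # records a format could not represent
    paths: list[str] = field(default_factory=list)


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def _reader(store, dataset, variant_ids, q):
    try:
        for chunk in range(dataset.n_chunks):
            rows = store.chunk_variant_rows(dataset, chunk)
            runs = store.load_chunk_runs(dataset, chunk)
            batch = []
            for (idx, rec, _e, _g), run in zip(rows, runs):
                if variant_ids is None or rec.variant_id in variant_ids:
                    batch.append((rec, run))
            q.put(batch)
    finally:
        q.put(_SENTINEL)


def export(
    store: VariantStore,
    dataset: DatasetDescriptor,
    out_path,
    fmt: str = "vcf",
    variant_ids: Optional[Sequence[str]] = None,
    individuals: Optional[Sequence[str]] = None,
    progress: Optional[Callable[[int, int], None]] = None,
) -> ExportSummary:
    """Write the selected variants x individuals submatrix to ``out_path``.

    ``variant_ids=None`` exports the whole dataset; ``individuals=None``
    exports every individual.
    """
    if fmt not in FORMATS:
        raise ValidationError(f"unknown format {fmt!r}; choose from {FORMATS}")
    inds = list(individuals) if individuals is not None else list(dataset.individuals)
    bad = set(inds) - set(dataset.individuals)
    if bad:
        raise ValidationError(f"unknown individual(s): {sorted(bad)[:5]}")
    idset = set(variant_ids) if variant_ids is not None else None

    q: queue.Queue = queue.Queue(maxsize=_BUFFER_CHUNKS)
    t = threading.Thread(target=_reader, args=(store, dataset, idset, q), daemon=True)
    t.start()

    writer = {
        "vcf": _VcfWriter,
        "plink": _PlinkWriter,
        "hapmap": _HapmapWriter,
        "flapjack": _FlapjackWriter,
    }[fmt](Path(out_path), dataset, inds)
    n = 0
    chunks_done = 0
    with writer:
        while True:
            batch = q.get()
            if batch is _SENTINEL:
                break
            for rec, run in batch:
                writer.write(rec, run)
                n += 1
            chunks_done += 1
            if progress:
                progress(chunks_done, dataset.n_chunks)
    t.join()
    return ExportSummary(n, len(inds), writer.skipped, writer.paths)


class _Writer:
    def __init__(self, path: Path, dataset: DatasetDescriptor, individuals: list[str]):
        self.path = path
        self.dataset = dataset
        self.individuals = individuals
        self.skipped = 0
        self.paths: list[str] = [str(path)]

    def __enter__(self):
        self.open()
        return self

    def __exit__(self, *exc):
        self.close()

    def open(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def write(self, rec: VariantRecord, run: GenotypeRun):
        raise NotImplementedError

    def close(self):
        raise NotImplementedError


class _VcfWriter(_Writer):
    def open(self):
        d = self.dataset
        self.fh = _open_text(self.path)
        lines = ["##fileformat=VCFv4.2", f"##source=genoquery"]
        for seq in d.sequences:
            lines.append(f"##contig=<ID={seq}>")
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        self.fields = sorted(d.numeric_fields)
        for f in self.fields:
            lines.append(
                f'##FORMAT=<ID={f},Number=1,Type={d.numeric_fields[f]},Description="{f}">'
            )
        if d.annotation_source == "snpeff":
            lines.append(
                '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations:'
                " 'Allele | Annotation | Annotation_Impact | Gene_Name'\">"
            )
        elif d.annotation_source == "vep":
            lines.append(
                '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations.'
                ' Format: Allele|Consequence|IMPACT|SYMBOL">'
            )
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(self.individuals)
        )
        self.fh.write("\n".join(lines) + "\n")

    def write(self, rec, run):
        ref = rec.known_alleles[0]
        alt = ",".join(rec.known_alleles[1:]) if rec.n_alleles > 1 else "."
        info = "."
        if run.annotations:
            entries = [f"{a.allele}|{a.effect}|{a.impact}|{a.gene_name}" for a in run.annotations]
            key = "CSQ" if self.dataset.annotation_source == "vep" else "ANN"
            info = f"{key}=" + ",".join(entries)
        fmt = ":".join(["GT"] + self.fields)
        cols = []
        for ind in self.individuals:
            call = run.calls.get(ind)
            gt = call.to_string() if call else ("." if self.dataset.ploidy == 1 else "./.")
            vals = run.numeric_values.get(ind, {})
            parts = [gt] + [str(vals[f]) if f in vals else "." for f in self.fields]
            cols.append(":".join(parts))
        self.fh.write(
            f"{rec.sequence}\t{rec.position}\t{rec.variant_id}\t{ref}\t{alt}\t.\t.\t{info}\t{fmt}\t"
            + "\t".join(cols)
            + "\n"
        )

    def close(self):
        self.fh.close()


class _PlinkWriter(_Writer):
    def open(self):
        base = str(self.path)
        for suffix in (".ped", ".map"):
            if base.endswith(suffix):
                base = base[: -len(suffix)]
        self.ped_path, self.map_path = base + ".ped", base + ".map"
        self.paths = [self.ped_path, self.map_path]
        self.map_fh = open(self.map_path, "w")
        # PED is individual-major: buffer per-individual allele columns
        self.geno: dict[str, list[str]] = {i: [] for i in self.individuals}

    def write(self, rec, run):
        self.map_fh.write(f"{rec.sequence}\t{rec.variant_id}\t0\t{rec.position}\n")
        alleles = rec.known_alleles
        for ind in self.individuals:
            call = run.calls.get(ind)
            if call is None:
                self.geno[ind].append("0\t0")
            else:
                idx = list(call.allele_indices)
                if len(idx) == 1:
                    idx = idx * 2  # haploid shown as homozygous diploid
                self.geno[ind].append(f"{alleles[idx[0]]}\t{alleles[idx[1]]}")

    def close(self):
        self.map_fh.close()
        with open(self.ped_path, "w") as fh:
            for ind in self.individuals:
                fh.write("\t".join([ind, ind, "0", "0", "0", "-9"] + self.geno[ind]) + "\n")


class _HapmapWriter(_Writer):
    def open(self):
        self.fh = _open_text(self.path)
        self.fh.write("\t".join(HAPMAP_COLUMNS + self.individuals) + "\n")

    def write(self, rec, run):
        if rec.variant_type != "SNP":
            self.skipped += 1  # single-letter cells cannot carry indels/MNPs
            return
        alleles = rec.known_alleles
        cells = []
        for ind in self.individuals:
            call = run.calls.get(ind)
            if call is None:
                cells.append("NN")
            else:
                cells.append("".join(alleles[i] for i in call.allele_indices))
        row = [
            rec.variant_id, "/".join(alleles), rec.sequence, str(rec.position),
            "+", "NA", "NA", "NA", "NA", "NA", "NA",
        ]
        self.fh.write("\t".join(row + cells) + "\n")

    def close(self):
        self.fh.close()


class _FlapjackWriter(_Writer):
    GENOTYPE_MEMBER = "genotypes.txt"
    MAP_MEMBER = "map.txt"

    def open(self):
        self.markers: list[str] = []
        self.map_rows: list[str] = []
        self.geno: dict[str, list[str]] = {i: [] for i in self.individuals}

    def write(self, rec, run):
        self.markers.append(rec.variant_id)
        self.map_rows.append(f"{rec.variant_id}\t{rec.sequence}\t{rec.position}")
        alleles = rec.known_alleles
        for ind in self.individuals:
            call = run.calls.get(ind)
            if call is None:
                self.geno[ind].append("")
            else:
                self.geno[ind].append("/".join(alleles[i] for i in call.allele_indices))

    def close(self):
        with zipfile.ZipFile(self.path, "w", zipfile.ZIP_DEFLATED) as zf:
            geno_lines = ["# fjFile = GENOTYPE", "\t" + "\t".join(self.markers)]
            for ind in self.individuals:
                geno_lines.append(ind + "\t" + "\t".join(self.geno[ind]))
            zf.writestr(self.GENOTYPE_MEMBER, "\n".join(geno_lines) + "\n")
            zf.writestr(
                self.MAP_MEMBER, "\n".join(["# fjFile = MAP"] + self.map_rows) + "\n"
            )
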