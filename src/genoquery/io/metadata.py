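"""Individual-metadata TSV import and attachment to a dataset.

The file is tab-separated with a header row; the first column holds the
individual id and the remaining header names become attribute names,
preserved verbatim.  Rows for individuals unknown to the dataset are
reported and skipped, not fatal — metadata files often cover a superset of
the genotyped panel.
"""

from __future__ import annotations

import json
from typing import Optional

from ..model import DatasetDescriptor, IndividualMetadata, ParseError, ValidationError
from ..store import VariantStore

METADATA_FILE = "metadata.json"


def read_metadata_tsv(path) -> list[IndividualMetadata]:
    out: list[IndividualMetadata] = []
    seen = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 1 or not header[0]:
            raise ParseError(f"{path}: missing header row")
        attrs = header[1:]
        for ln, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            ind = parts[0]
            if ind in seen:
                raise ValidationError(f"{path}: line {ln}: duplicate individual row {ind!r}")
            seen.add(ind)
            values = parts[1:] + [""] * (len(attrs) - len(parts) + 1)
            out.append(IndividualMetadata(ind, dict(zip(attrs, values))))
    return out


def attach_metadata(
    store: VariantStore, dataset: DatasetDescriptor, metas: list[IndividualMetadata]
) -> list[str]:
    """Persist metadata for a dataset; returns ids skipped as unknown."""
    known = set(dataset.individuals)
    skipped = [m.individual_id for m in metas if m.individual_id not in known]
    payload = {m.individual_id: m.attributes for m in metas if m.individual_id in known}
    (store.root / dataset.name / METADATA_FILE).write_text(json.dumps(payload, indent=1))
    return skipped


def load_metadata(store: VariantStore, dataset: DatasetDescriptor) -> dict[str, dict[str, str]]:
    p = store.root / dataset.name / METADATA_FILE
    return json.loads(p.read_text()) if p.exists() else {}


def select_individuals(
    store: VariantStore, dataset: DatasetDescriptor, attribute: str, value: str
) -> list[str]:
    """Ids of individuals whose metadata attribute equals ``value``, dataset order."""
    meta = load_metadata(store, dataset)
    return [i for i in dataset.individuals if meta.get(i, {}).get(attribute) == value]
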