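"""Readers and writers for the tabular formats the pipeline touches.

All tables are delimiter-separated text (TSV by default). Filtering
readers never fail on bad rows: they warn, count, and keep going — the
pipeline's own preprocessing is a sequence of filters, so a rejected row
is an expected event, not an error. Structural problems (missing
columns, duplicate ids) do raise.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

from ddinet.core import (
    DDISet,
    PPIRecord,
    Protein,
    ProteinCatalog,
    ReaderLog,
    validate_disorder_table,
)

logger = logging.getLogger(__name__)

PFAM_RE = re.compile(r"^PF\d{5}(\.\d+)?$")

#: default column names for protein catalog tables
CATALOG_COLUMNS = {
    "id": "id",
    "organism": "organism",
    "pfam_ids": "pfam_ids",
    "gene_name": "gene_name",
    "tissues": "tissues",
}


def _read_rows(path: str | Path, sep: str) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        rows = [row for row in reader if row]
    if not rows:
        return [], []
    return rows[0], rows[1:]


def read_protein_catalog(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str = "\t",
    list_delim: str = ";",
) -> ProteinCatalog:
    """Read a protein catalog table into a :class:`ProteinCatalog`.

    Mandatory columns: id, organism, pfam_ids (``list_delim``-separated).
    Optional: gene_name, tissues. Rows without any Pfam ID are rejected
    (logged on ``catalog.rejected``) because downstream embedding and
    classification are domain-based and cannot represent them.
    """
    cols = dict(CATALOG_COLUMNS)
    if columns:
        cols.update(columns)
    header, rows = _read_rows(path, sep)
    for mandatory in ("id", "organism", "pfam_ids"):
        if cols[mandatory] not in header:
            raise ValueError(f"catalog is missing mandatory column {cols[mandatory]!r}")
    idx = {k: header.index(v) for k, v in cols.items() if v in header}

    catalog = ProteinCatalog()
    seen: dict[str, int] = {}
    duplicates = []
    for rowno, row in enumerate(rows, start=2):
        pid = row[idx["id"]].strip()
        if pid in seen:
            duplicates.append(pid)
            continue
        seen[pid] = rowno
        pfams = tuple(t for t in row[idx["pfam_ids"]].split(list_delim) if t.strip())
        if not pfams:
            catalog.rejected.append((rowno, pid))
            continue
        gene = row[idx["gene_name"]].strip() if "gene_name" in idx else ""
        tissues = frozenset(
            t.strip()
            for t in (row[idx["tissues"]].split(list_delim) if "tissues" in idx else [])
            if t.strip()
        )
        catalog.add(
            Protein(id=pid, organism=row[idx["organism"]].strip(), pfam_ids=pfams,
                    gene_name=gene, tissues=tissues)
        )
    if duplicates:
        raise ValueError(f"duplicate protein ids in catalog: {sorted(set(duplicates))}")
    if catalog.rejected:
        logger.warning(
            "rejected %d catalog rows without Pfam IDs", len(catalog.rejected)
        )
    return catalog


def write_protein_catalog(catalog: ProteinCatalog, path: str | Path,
                          sep: str = "\t", list_delim: str = ";") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["id", "organism", "pfam_ids", "gene_name", "tissues"])
        for p in sorted(catalog, key=lambda p: p.id):
            w.writerow([
                p.id, p.organism, list_delim.join(p.pfam_ids), p.gene_name,
                list_delim.join(sorted(p.tissues)),
            ])


def read_ppi_table(
    path: str | Path,
    catalog: ProteinCatalog | None = None,
    sep: str = "\t",
) -> tuple[list[PPIRecord], ReaderLog]:
    """Read a protein-pair table; drop pairs whose endpoints are unusable.

    A record is kept only when both endpoints are present in ``catalog``
    and carry at least one Pfam ID (pass ``catalog=None`` to skip the
    check). Duplicates under unordered identity are collapsed, keeping
    the first occurrence. Returns the records plus a log whose counts
    satisfy ``n_read == n_kept + n_dropped``.
    """
    header, rows = _read_rows(path, sep)
    if len(header) < 2:
        raise ValueError("PPI table needs at least two columns (a, b)")
    has_label = "label" in header
    has_source = "source" in header
    label_i = header.index("label") if has_label else None
    source_i = header.index("source") if has_source else None

    log = ReaderLog()
    records: list[PPIRecord] = []
    seen: set[tuple[str, str]] = set()
    for rowno, row in enumerate(rows, start=2):
        log.n_read += 1
        if len(row) < 2 or not row[0].strip() or not row[1].strip():
            logger.warning("skipping unreadable PPI row %d", rowno)
            log.dropped.append(f"row {rowno}: unreadable")
            continue
        a, b = row[0].strip(), row[1].strip()
        if catalog is not None:
            bad = [x for x in (a, b) if x not in catalog or not catalog[x].embeddable]
            if bad:
                log.dropped.append(f"row {rowno}: unusable endpoint {bad[0]}")
                continue
        label = row[label_i].strip() if has_label and len(row) > label_i else "unlabeled"
        source = row[source_i].strip() if has_source and len(row) > source_i else ""
        rec = PPIRecord(a, b, label=label or "unlabeled", source=source)
        if rec.key in seen:
            log.dropped.append(f"row {rowno}: duplicate pair {rec.key}")
            continue
        seen.add(rec.key)
        records.append(rec)
        log.n_kept += 1
    assert log.n_read == log.n_kept + log.n_dropped
    return records, log


def write_ppi_table(records: Iterable[PPIRecord], path: str | Path,
                    sep: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["a", "b", "label", "source"])
        for r in sorted(records, key=lambda r: r.key):
            w.writerow([r.a, r.b, r.label, r.source])


def read_ddi_table(path: str | Path, sep: str = "\t",
                   validate_accessions: bool = True) -> DDISet:
    """Read a two-column table of Pfam pairs into an order-insensitive multiset."""
    header, rows = _read_rows(path, sep)
    ddis = DDISet()
    for rowno, row in enumerate(rows, start=2):
        if len(row) < 2:
            logger.warning("skipping malformed DDI row %d", rowno)
            continue
        a, b = row[0].strip(), row[1].strip()
        if validate_accessions and not (PFAM_RE.match(a) and PFAM_RE.match(b)):
            logger.warning("skipping DDI row %d with malformed accession", rowno)
            continue
        ddis.add(a, b)
    return ddis


def write_ddi_table(ddis: DDISet, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["pfam_a", "pfam_b"])
        for (a, b), count in sorted(ddis.items()):
            for _ in range(count):
                w.writerow([a, b])


def read_strain_abundances(path: str | Path, sep: str = "\t") -> dict[str, float]:
    header, rows = _read_rows(path, sep)
    out: dict[str, float] = {}
    for row in rows:
        if len(row) < 2:
            continue
        value = float(row[1])
        if value < 0:
            raise ValueError(f"negative abundance for strain {row[0]}")
        out[row[0].strip()] = value
    return out


def write_strain_abundances(abundances: Mapping[str, float], path: str | Path,
                            sep: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["strain", "abundance"])
        for strain in sorted(abundances):
            w.writerow([strain, repr(float(abundances[strain]))])


def read_disorder_table(path: str | Path, sep: str = "\t") -> dict[str, float]:
    header, rows = _read_rows(path, sep)
    raw = {row[0].strip(): float(row[1]) for row in rows if len(row) >= 2}
    return validate_disorder_table(raw)


def write_disorder_table(table: Mapping[str, float], path: str | Path,
                         sep: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["id", "disorder_fraction"])
        for pid in sorted(table):
            w.writerow([pid, repr(float(table[pid]))])


def read_cluster_map(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Read a protein-id -> cluster-id map (UniRef90-style, precomputed)."""
    header, rows = _read_rows(path, sep)
    return {row[0].strip(): row[1].strip() for row in rows if len(row) >= 2}


def write_edge_list(network, path: str | Path, with_scores: bool = True,
                    sep: str = "\t") -> None:
    """Write a bipartite network as a (bacterial, host[, score]) TSV.

    Rows are sorted lexicographically so repeated runs diff cleanly.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        header = ["bacterial", "host"] + (["score"] if with_scores else [])
        w.writerow(header)
        for (bact, host), score in sorted(network.edges.items()):
            row = [bact, host] + ([repr(float(score))] if with_scores else [])
            w.writerow(row)


def read_edge_list(path: str | Path, sep: str = "\t") -> list[tuple[str, str, float | None]]:
    """Read an edge list written by :func:`write_edge_list`."""
    header, rows = _read_rows(path, sep)
    out = []
    for row in rows:
        if len(row) < 2:
            continue
        score = float(row[2]) if len(row) > 2 and row[2] else None
        out.append((row[0].strip(), row[1].strip(), score))
    return out
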