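"""Per-gene functional annotations from heterogeneous prediction methods.

Two output dialects are ingested: score-carrying GO prediction tables
from structure/sequence deep-learning annotators (one row per gene-term
pair with a confidence in [0, 1]) and orthology-mapper annotation TSVs
(one row per gene, GO ids comma-packed in one column, plus a free-text
description).  Orthology calls carry no score and are recorded as 1.0.

Score thresholds follow the annotator's published confidence bands:
0.2 = standard quality, 0.5 = high quality; rows below the active
threshold are dropped at read time.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Mapping

from .errors import FormatError
from .go_dag import GO_ACCESSION_RE, GoDag, propagate_up

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationRecord:
    gene_id: str
    term: str
    score: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score out of [0,1]: {self.score}")
        if not GO_ACCESSION_RE.match(self.term):
            raise ValueError(f"not a GO accession: {self.term!r}")


class AnnotationSet:
    """Records grouped by gene, with duplicate (gene, term, method) rows
    collapsed keeping the maximum score, plus optional per-gene free-text
    descriptions.  A gene with a description is part of the set even when
    it carries no GO record."""

    def __init__(
        self,
        records: Iterable[AnnotationRecord] = (),
        descriptions: Mapping[str, str] | None = None,
    ):
        self._by_gene: dict[str, dict[tuple[str, str], float]] = {}
        self.descriptions: dict[str, str] = dict(descriptions or {})
        for rec in records:
            self.add(rec)

    def add(self, rec: AnnotationRecord) -> None:
        slot = self._by_gene.setdefault(rec.gene_id, {})
        key = (rec.term, rec.method)
        if rec.score >= slot.get(key, -1.0):
            slot[key] = rec.score

    def records(self) -> Iterator[AnnotationRecord]:
        for gene in sorted(self._by_gene):
            for (term, method), score in sorted(self._by_gene[gene].items()):
                yield AnnotationRecord(gene, term, score, method)

    def genes(self, method: str | None = None) -> set[str]:
        """Genes carrying >= 1 GO record (for ``method`` if given)."""
        if method is None:
            return set(self._by_gene)
        return {
            g
            for g, slot in self._by_gene.items()
            if any(m == method for _, m in slot)
        }

    def described_genes(self) -> set[str]:
        return {g for g, d in self.descriptions.items() if d}

    def terms_for(self, gene_id: str, method: str | None = None) -> set[str]:
        slot = self._by_gene.get(gene_id, {})
        return {t for t, m in slot if method is None or m == method}

    def score_of(self, gene_id: str, term: str, method: str) -> float | None:
        return self._by_gene.get(gene_id, {}).get((term, method))

    def methods(self) -> set[str]:
        return {m for slot in self._by_gene.values() for _, m in slot}

    def __len__(self) -> int:
        return sum(len(slot) for slot in self._by_gene.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_gene or gene_id in self.descriptions

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AnnotationSet)
            and self._by_gene == other._by_gene
            and self.descriptions == other.descriptions
        )


@dataclass(frozen=True)
class AnnotationConfig:
    """Score thresholds for structure-based GO predictions."""

    standard_threshold: float = 0.2
    high_threshold: float = 0.5
    active_threshold: float = 0.2

    def __post_init__(self) -> None:
        for v in (self.standard_threshold, self.high_threshold, self.active_threshold):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold out of [0,1]: {v}")


def _open_text(source: str | IO[str]) -> IO[str]:
    if isinstance(source, str):
        if "\n" in source or not source:
            return io.StringIO(source)
        return open(source)
    return source


def _looks_like_header(row: list[str]) -> bool:
    if len(row) < 3:
        return True
    try:
        float(row[2])
    except ValueError:
        return True
    return not GO_ACCESSION_RE.match(row[1].strip())


def read_structure_prediction_table(
    source: str | IO[str],
    cfg: AnnotationConfig = AnnotationConfig(),
    method: str = "deepfri",
) -> AnnotationSet:
    """Read a delimited (gene, GO term, score[, term name]) table.

    Comma- and tab-delimited dialects are auto-detected; an optional
    header row is recognised and skipped.  Rows with score below
    ``cfg.active_threshold`` are dropped (kept when score >= threshold);
    the number dropped is logged.
    """
    handle = _open_text(source)
    try:
        text = handle.read()
    finally:
        if isinstance(source, str) and "\n" not in source:
            handle.close()
    if not text.strip():
        return AnnotationSet()
    first = text.splitlines()[0]
    if "\t" in first:
        delim = "\t"
    elif "," in first:
        delim = ","
    else:
        raise FormatError("cannot detect delimiter (expected comma or tab)")

    out = AnnotationSet()
    dropped = 0
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    for line_no, row in enumerate(reader, start=1):
        if not row or not "".join(row).strip():
            continue
        if line_no == 1 and _looks_like_header(row):
            continue
        if len(row) < 3:
            raise FormatError(f"line {line_no}: expected >= 3 columns, got {len(row)}")
        gene, term = row[0].strip(), row[1].strip()
        try:
            score = float(row[2])
        except ValueError as exc:
            raise FormatError(f"line {line_no}: unparseable score {row[2]!r}") from exc
        if score < cfg.active_threshold:
            dropped += 1
            continue
        out.add(AnnotationRecord(gene, term, score, method))
    if dropped:
        logger.info("dropped %d rows below score threshold %.2f", dropped, cfg.active_threshold)
    return out


_GO_LIST_RE = re.compile(r"GO:\d{7}")


def read_orthology_table(
    source: str | IO[str],
    go_column: str | int = "GOs",
    description_column: str | int = "eggNOG free text desc.",
    method: str = "eggnog",
) -> AnnotationSet:
    """Read an orthology-mapper ``.annotations`` TSV.

    Lines starting with ``#`` are comments; the last comment line that
    tab-splits into multiple fields is taken as the header.  The GO
    column (comma-separated accessions; ``-`` or empty = none) is
    exploded to one record per term at score 1.0; the free-text
    description column is captured per gene.  Columns are located by
    header name when a header is present, else by integer index.
    """
    handle = _open_text(source)
    try:
        lines = handle.read().splitlines()
    finally:
        if isinstance(source, str) and "\n" not in source:
            handle.close()

    header: list[str] | None = None
    data_rows: list[tuple[int, list[str]]] = []
    for line_no, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = line.lstrip("#").split("\t")
            if len(fields) > 1:
                header = [f.strip() for f in fields]
            continue
        data_rows.append((line_no, line.split("\t")))

    def resolve(col: str | int) -> int | None:
        if isinstance(col, int):
            return col
        if header is None:
            return None
        try:
            return header.index(col)
        except ValueError:
            return None

    go_idx = resolve(go_column)
    if go_idx is None:
        raise FormatError(
            f"cannot locate GO column {go_column!r}: provide a header line "
            "naming it or pass an integer column index"
        )
    desc_idx = resolve(description_column)

    out = AnnotationSet()
    for line_no, row in data_rows:
        gene = row[0].strip()
        raw_go = row[go_idx].strip() if go_idx < len(row) else ""
        if raw_go and raw_go != "-":
            for term in raw_go.split(","):
                term = term.strip()
                if not term:
                    continue
                out.add(AnnotationRecord(gene, term, 1.0, method))
        desc = ""
        if desc_idx is not None and desc_idx < len(row):
            desc = row[desc_idx].strip()
            if desc == "-":
                desc = ""
        if desc:
            out.descriptions[gene] = desc
    return out


def filter_informative(
    annots: AnnotationSet,
    informative: set[str],
    dag: GoDag,
) -> AnnotationSet:
    """Project annotations onto the informative-term antichain.

    Each gene's term set (per method) is propagated upward and
    intersected with ``informative``; the gene keeps the informative
    ancestors reached, at the maximum score among its contributing
    records.  Genes whose closure misses the informative set entirely
    are dropped.  Idempotent, because informative terms map to
    themselves under closure-and-intersect.
    """
    out = AnnotationSet()
    for gene in annots.genes():
        kept = False
        for m in annots.methods():
            terms = annots.terms_for(gene, m)
            if not terms:
                continue
            closure = propagate_up(dag, terms, on_missing="drop")
            hits = closure & informative
            if not hits:
                continue
            kept = True
            best = max(annots.score_of(gene, t, m) or 0.0 for t in terms)
            for h in hits:
                out.add(AnnotationRecord(gene, h, best, m))
        if kept and gene in annots.descriptions:
            out.descriptions[gene] = annots.descriptions[gene]
    return out


def write_long_tsv(annots: AnnotationSet, handle: IO[str] | None = None) -> str:
    """Canonical long-format TSV: gene_id, term, score, method."""
    buf = io.StringIO()
    buf.write("gene_id\tterm\tscore\tmethod\n")
    for rec in annots.records():
        buf.write(f"{rec.gene_id}\t{rec.term}\t{rec.score:.6g}\t{rec.method}\n")
    text = buf.getvalue()
    if handle is not None:
        handle.write(text)
    return text


def read_long_tsv(source: str | IO[str]) -> AnnotationSet:
    handle = _open_text(source)
    try:
        lines = handle.read().splitlines()
    finally:
        if isinstance(source, str) and "\n" not in source:
            handle.close()
    out = AnnotationSet()
    for line_no, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("gene_id\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"line {line_no}: expected 4 columns")
        out.add(AnnotationRecord(parts[0], parts[1], float(parts[2]), parts[3]))
    return out
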