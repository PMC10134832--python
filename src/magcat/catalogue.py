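"""The nonredundant gene catalogue.

Predicted genes from all samples are clustered at 95% sequence identity;
each cluster is represented by a centroid sequence.  Functional
annotations are computed on centroids only and propagated to every
cluster member, so the catalogue's gene -> cluster index is the join key
for all downstream integration.

Gene ids follow the gene-caller convention ``<contig_id>_<ordinal>``;
the contig id is recovered by splitting on the LAST underscore, since
contig names themselves may contain underscores.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .annotations import AnnotationRecord, AnnotationSet
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    """A predicted gene on an assembled contig."""

    gene_id: str
    sample_id: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"gene {self.gene_id}: length must be > 0")
        if "_" not in self.gene_id:
            raise ValidationError(
                f"gene id {self.gene_id!r} lacks the <contig>_<n> structure"
            )

    @property
    def contig_id(self) -> str:
        return self.gene_id.rsplit("_", 1)[0]


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: str
    centroid: str
    members: frozenset[str]
    identity_threshold: float = 0.95

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"cluster {self.cluster_id} has no members")
        if self.centroid not in self.members:
            raise ValidationError(
                f"cluster {self.cluster_id}: centroid {self.centroid} not a member"
            )

    @property
    def size(self) -> int:
        return len(self.members)


class GeneCatalogue:
    """Clusters plus the inverse gene -> cluster index.

    Clusters must partition the gene universe: a gene id may appear in
    exactly one cluster.
    """

    def __init__(self, clusters: Iterable[GeneCluster]):
        self.clusters: dict[str, GeneCluster] = {}
        self.gene_index: dict[str, str] = {}
        for cl in clusters:
            if cl.cluster_id in self.clusters:
                raise ValidationError(f"duplicate cluster id {cl.cluster_id}")
            self.clusters[cl.cluster_id] = cl
            for g in cl.members:
                if g in self.gene_index:
                    raise ValidationError(
                        f"gene {g} appears in clusters "
                        f"{self.gene_index[g]} and {cl.cluster_id}"
                    )
                self.gene_index[g] = cl.cluster_id

    @property
    def n_genes(self) -> int:
        return len(self.gene_index)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def centroids(self) -> set[str]:
        return {cl.centroid for cl in self.clusters.values()}

    def cluster_of(self, gene_id: str) -> str | None:
        return self.gene_index.get(gene_id)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneCatalogue) and self.clusters == other.clusters


_CLSTR_HEADER_RE = re.compile(r"^>Cluster\s+(\d+)")
_CLSTR_MEMBER_RE = re.compile(
    r"^(\d+)\s+(\d+)(aa|nt),\s+>(?P<gene>.*?)\.\.\.\s+(?P<tail>.*)$"
)


def parse_clstr(source: str | IO[str]) -> GeneCatalogue:
    """Parse greedy-incremental clustering ``.clstr`` output.

    Each ``>Cluster N`` block lists member lines of the form
    ``<idx>\\t<len>aa, ><gene_id>... <at identity | *>`` with exactly one
    ``*`` (representative) per cluster.  Gene ids are stored truncated
    exactly as the tool truncates them (everything before ``...``).
    """
    if isinstance(source, str):
        lines = (
            io.StringIO(source).read().splitlines()
            if "\n" in source
            else open(source).read().splitlines()
        )
    else:
        lines = source.read().splitlines()

    clusters: list[GeneCluster] = []
    cur_id: str | None = None
    members: list[str] = []
    centroid: str | None = None

    def flush() -> None:
        nonlocal centroid
        if cur_id is None:
            return
        if centroid is None:
            raise FormatError(f"cluster {cur_id} has no representative ('*') line")
        clusters.append(
            GeneCluster(
                cluster_id=f"Cluster_{cur_id}",
                centroid=centroid,
                members=frozenset(members),
            )
        )

    for line_no, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        m = _CLSTR_HEADER_RE.match(line)
        if m:
            flush()
            cur_id = m.group(1)
            members = []
            centroid = None
            continue
        if cur_id is None:
            raise FormatError(f"line {line_no}: member line before any cluster header")
        mm = _CLSTR_MEMBER_RE.match(line)
        if not mm:
            raise FormatError(f"line {line_no}: unrecognised member line {line!r}")
        gene = mm.group("gene")
        members.append(gene)
        if mm.group("tail").strip() == "*":
            if centroid is not None:
                raise FormatError(f"cluster {cur_id} has multiple '*' lines")
            centroid = gene
    flush()
    return GeneCatalogue(clusters)


def read_gene_fasta(
    source: str | IO[str],
    sample_of: Mapping[str, str] | None = None,
    id_width: int | None = None,
) -> list[GeneRecord]:
    """Read gene sequences; lengths from the sequences, ids truncated to
    ``id_width`` characters when given (mirroring the clustering tool's
    id truncation so joins against the ``.clstr`` file never fail).

    ``sample_of`` maps contig id -> sample id; unknown contigs get "".
    """
    if isinstance(source, str) and "\n" in source:
        handle: IO[str] = io.StringIO(source)
    elif isinstance(source, str):
        handle = open(source)
    else:
        handle = source
    out = []
    for rec in SeqIO.parse(handle, "fasta"):
        gid = rec.id if id_width is None else rec.id[:id_width]
        contig = gid.rsplit("_", 1)[0]
        sample = (sample_of or {}).get(contig, "")
        out.append(GeneRecord(gene_id=gid, sample_id=sample, length=len(rec.seq)))
    if isinstance(source, str):
        handle.close()
    return out


def propagate_cluster_annotations(
    cat: GeneCatalogue,
    centroid_annots: AnnotationSet,
    strict: bool = False,
) -> AnnotationSet:
    """Copy each centroid's annotation records to every cluster member.

    Annotation keys that are not centroids (or not in the catalogue) are
    ignored with a warning, or raise in strict mode.  Members of
    unannotated clusters are absent from the result.
    """
    centroids = cat.centroids()
    out = AnnotationSet()
    for gene in centroid_annots.genes() | centroid_annots.described_genes():
        if gene not in centroids:
            msg = f"annotation key {gene} is not a cluster centroid"
            if strict:
                raise ValidationError(msg)
            logger.warning("%s; skipping", msg)
            continue
        cluster = cat.clusters[cat.gene_index[gene]]
        desc = centroid_annots.descriptions.get(gene)
        for member in cluster.members:
            for m in centroid_annots.methods():
                for term in centroid_annots.terms_for(gene, m):
                    score = centroid_annots.score_of(gene, term, m)
                    out.add(AnnotationRecord(member, term, score, m))
            if desc:
                out.descriptions[member] = desc
    return out


def annotation_rate_by_cluster_size(
    cat: GeneCatalogue, annots: AnnotationSet
) -> pd.DataFrame:
    """Fraction of clusters of each size whose centroid is annotated.

    Returns a DataFrame with columns ``size``, ``n_clusters``,
    ``n_annotated``, ``fraction`` sorted by size.
    """
    annotated_genes = annots.genes()
    rows: dict[int, list[int]] = {}
    for cl in cat.clusters.values():
        tot, ann = rows.setdefault(cl.size, [0, 0])
        rows[cl.size][0] = tot + 1
        rows[cl.size][1] = ann + (1 if cl.centroid in annotated_genes else 0)
    df = pd.DataFrame(
        [
            {"size": s, "n_clusters": t, "n_annotated": a, "fraction": a / t}
            for s, (t, a) in sorted(rows.items())
        ]
    )
    return df


def write_catalogue_tsv(
    cat: GeneCatalogue,
    genes: Mapping[str, GeneRecord] | None = None,
    handle: IO[str] | None = None,
) -> str:
    """Serialize membership as TSV: gene_id, cluster_id, is_centroid,
    length, contig_id, sample_id (length/sample blank when unknown)."""
    buf = io.StringIO()
    buf.write("gene_id\tcluster_id\tis_centroid\tlength\tcontig_id\tsample_id\n")
    for cid in sorted(cat.clusters):
        cl = cat.clusters[cid]
        for g in sorted(cl.members):
            rec = (genes or {}).get(g)
            length = str(rec.length) if rec else ""
            sample = rec.sample_id if rec else ""
            contig = g.rsplit("_", 1)[0]
            flag = "1" if g == cl.centroid else "0"
            buf.write(f"{g}\t{cid}\t{flag}\t{length}\t{contig}\t{sample}\n")
    text = buf.getvalue()
    if handle is not None:
        handle.write(text)
    return text


def read_catalogue_tsv(source: str | IO[str]) -> GeneCatalogue:
    if isinstance(source, str):
        text = source if "\n" in source else open(source).read()
    else:
        text = source.read()
    members: dict[str, set[str]] = {}
    centroid: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("gene_id\t"):
            continue
        g, cid, flag = line.split("\t")[:3]
        members.setdefault(cid, set()).add(g)
        if flag == "1":
            centroid[cid] = g
    return GeneCatalogue(
        GeneCluster(cid, centroid[cid], frozenset(ms)) for cid, ms in members.items()
    )
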