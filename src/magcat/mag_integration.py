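"""Integration of the gene catalogue with metagenome-assembled genomes.

MAGs arrive as bins of contigs with single-copy-marker quality estimates
(completeness, contamination) and a 7-rank taxonomy string in GTDB
prefix notation.  "Nearly complete" genomes (>= 90% completeness and
< 5% contamination) drive the pangenome analyses; the multi-taxonomy
gene-family analysis uses only the contamination filter.

Genes are tied to MAGs through contig membership: a gene belongs to the
MAG whose bin contains its contig, and to no MAG when the contig was
left unbinned.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import pandas as pd

from .annotations import AnnotationSet
from .catalogue import GeneCatalogue, GeneRecord
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class_", "order", "family", "genus", "species")
_GTDB_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass(frozen=True)
class TaxonomyLabel:
    """Seven-rank taxonomy with GTDB prefixes stripped; empty = unassigned.

    The ranks are hierarchical: once a rank is unassigned, all lower
    ranks are forced to unassigned as well.
    """

    domain: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    @classmethod
    def from_gtdb(cls, classification: str) -> "TaxonomyLabel":
        values = dict.fromkeys(RANKS, "")
        if classification.strip():
            for part in classification.split(";"):
                part = part.strip()
                for rank, prefix in zip(RANKS, _GTDB_PREFIXES):
                    if part.startswith(prefix):
                        values[rank] = part[len(prefix):].strip()
                        break
        # enforce hierarchy: blank out everything below the first gap
        seen_gap = False
        for rank in RANKS:
            if seen_gap:
                values[rank] = ""
            elif not values[rank]:
                seen_gap = True
        return cls(**values)

    def rank(self, name: str) -> str:
        name = "class_" if name == "class" else name
        if name not in RANKS:
            raise ValueError(f"unknown rank {name!r}")
        return getattr(self, name)

    def to_gtdb(self) -> str:
        return ";".join(
            prefix + self.rank(rank) for rank, prefix in zip(RANKS, _GTDB_PREFIXES)
        )


@dataclass(frozen=True)
class MagRecord:
    mag_id: str
    sample_id: str
    contigs: frozenset[str]
    completeness: float
    contamination: float
    taxonomy: TaxonomyLabel = TaxonomyLabel()

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValidationError(f"MAG {self.mag_id} has no contigs")
        if not 0.0 <= self.completeness <= 100.0:
            raise ValidationError(
                f"MAG {self.mag_id}: completeness {self.completeness} outside [0,100]"
            )
        if self.contamination < 0.0:
            raise ValidationError(
                f"MAG {self.mag_id}: negative contamination {self.contamination}"
            )


@dataclass(frozen=True)
class MagFilterConfig:
    """Nearly-complete genome thresholds: completeness inclusive,
    contamination exclusive (>= 90%, < 5%)."""

    min_completeness: float = 90.0
    max_contamination: float = 5.0

    def __post_init__(self) -> None:
        for v in (self.min_completeness, self.max_contamination):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"threshold outside [0,100]: {v}")


def _read_text(source: str | IO[str]) -> str:
    if isinstance(source, str):
        return source if "\n" in source else open(source).read()
    return source.read()


def read_bin_membership(source: str | IO[str]) -> dict[str, set[str]]:
    """Read a two-column (contig_id, mag_id) TSV into mag -> contig set."""
    bins: dict[str, set[str]] = {}
    for line_no, line in enumerate(_read_text(source).splitlines(), start=1):
        if not line.strip() or line.startswith("contig_id\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"bin membership line {line_no}: expected 2 columns")
        contig, mag = parts
        bins.setdefault(mag, set()).add(contig)
    return bins


def _find_column(columns: Iterable[str], *candidates: str) -> str:
    lowered = {c.lower().replace(" ", "").replace("_", ""): c for c in columns}
    for cand in candidates:
        key = cand.lower().replace(" ", "").replace("_", "")
        if key in lowered:
            return lowered[key]
    raise FormatError(f"none of the expected columns {candidates} present")


def read_mag_metadata(
    checkm_source: str | IO[str],
    gtdb_source: str | IO[str] | None,
    bins: Mapping[str, set[str]],
    sample_of: Mapping[str, str] | None = None,
    strict: bool = False,
) -> list[MagRecord]:
    """Combine quality-control and taxonomy tables with bin membership.

    The QC table must carry bin id, completeness and contamination
    columns; the taxonomy table carries ``user_genome`` and
    ``classification``.  Bins absent from the taxonomy table get an
    empty label (logged); bins absent from the QC table raise in strict
    mode and are skipped otherwise.  ``sample_of`` maps mag id to sample
    id; by default the sample is everything before the last underscore
    of the mag id (the ``<sample>_binN`` binning convention).
    """
    checkm = pd.read_csv(io.StringIO(_read_text(checkm_source)), sep="\t")
    bin_col = _find_column(checkm.columns, "Bin Id", "bin_id", "Name")
    comp_col = _find_column(checkm.columns, "Completeness")
    cont_col = _find_column(checkm.columns, "Contamination")
    qc = {
        str(r[bin_col]): (float(r[comp_col]), float(r[cont_col]))
        for _, r in checkm.iterrows()
    }

    taxonomy: dict[str, TaxonomyLabel] = {}
    if gtdb_source is not None:
        gtdb = pd.read_csv(io.StringIO(_read_text(gtdb_source)), sep="\t")
        genome_col = _find_column(gtdb.columns, "user_genome")
        class_col = _find_column(gtdb.columns, "classification")
        for _, r in gtdb.iterrows():
            taxonomy[str(r[genome_col])] = TaxonomyLabel.from_gtdb(str(r[class_col]))

    out: list[MagRecord] = []
    for mag_id in sorted(bins):
        if mag_id not in qc:
            msg = f"MAG {mag_id} missing from the QC table"
            if strict:
                raise ValidationError(msg)
            logger.warning("%s; skipping", msg)
            continue
        comp, cont = qc[mag_id]
        if mag_id not in taxonomy:
            logger.info("MAG %s has no taxonomy assignment", mag_id)
        sample = (
            sample_of[mag_id]
            if sample_of is not None
            else mag_id.rsplit("_", 1)[0]
        )
        out.append(
            MagRecord(
                mag_id=mag_id,
                sample_id=sample,
                contigs=frozenset(bins[mag_id]),
                completeness=comp,
                contamination=cont,
                taxonomy=taxonomy.get(mag_id, TaxonomyLabel()),
            )
        )
    return out


def filter_near_complete(
    mags: Iterable[MagRecord], cfg: MagFilterConfig = MagFilterConfig()
) -> list[MagRecord]:
    """Keep MAGs with completeness >= min and contamination < max."""
    return [
        m
        for m in mags
        if m.completeness >= cfg.min_completeness
        and m.contamination < cfg.max_contamination
    ]


def map_genes_to_mags(
    genes: Iterable[GeneRecord], mags: Iterable[MagRecord]
) -> dict[str, str | None]:
    """Map each gene to the MAG containing its contig, or None if unbinned.

    Within a sample, a contig claimed by two MAGs is a binning
    inconsistency and raises.
    """
    contig_to_mag: dict[tuple[str, str], str] = {}
    for mag in mags:
        for contig in mag.contigs:
            key = (mag.sample_id, contig)
            if key in contig_to_mag and contig_to_mag[key] != mag.mag_id:
                raise ValidationError(
                    f"contig {contig} in sample {mag.sample_id} claimed by "
                    f"both {contig_to_mag[key]} and {mag.mag_id}"
                )
            contig_to_mag[key] = mag.mag_id
    return {
        g.gene_id: contig_to_mag.get((g.sample_id, g.contig_id))
        for g in genes
    }


def cluster_taxonomy_sharing(
    cat: GeneCatalogue,
    gene2mag: Mapping[str, str | None],
    mags: Iterable[MagRecord],
    rank: str,
    max_contamination: float = 5.0,
) -> dict[str, int]:
    """Distinct taxonomy labels per gene cluster at one rank.

    Counts, for each cluster, the number of distinct non-empty ``rank``
    labels among low-contamination MAGs (< ``max_contamination``) that
    contain at least one member gene.  Clusters touched by no qualifying
    MAG score 0; empty labels never count.
    """
    if rank not in ("family", "genus", "species"):
        raise ValueError(f"rank must be family, genus or species, got {rank!r}")
    label_of = {
        m.mag_id: m.taxonomy.rank(rank)
        for m in mags
        if m.contamination < max_contamination
    }
    out: dict[str, set[str]] = {cid: set() for cid in cat.clusters}
    for gene, mag_id in gene2mag.items():
        if mag_id is None or mag_id not in label_of:
            continue
        cid = cat.cluster_of(gene)
        if cid is None:
            continue
        label = label_of[mag_id]
        if label:
            out[cid].add(label)
    return {cid: len(labels) for cid, labels in out.items()}


def build_gene_mapper_table(
    cat: GeneCatalogue,
    gene2mag: Mapping[str, str | None],
    mags: Iterable[MagRecord],
    annots_by_method: Mapping[str, AnnotationSet] | None = None,
) -> pd.DataFrame:
    """One row per catalogue gene tying together cluster, MAG, taxonomy
    and per-method annotation summaries (semicolon-joined sorted terms).
    """
    tax_of = {m.mag_id: m.taxonomy.to_gtdb() for m in mags}
    annots_by_method = annots_by_method or {}
    rows = []
    for gene in sorted(cat.gene_index):
        cid = cat.gene_index[gene]
        mag_id = gene2mag.get(gene)
        row = {
            "gene_id": gene,
            "cluster_id": cid,
            "is_centroid": int(gene == cat.clusters[cid].centroid),
            "mag_id": mag_id or "",
            "taxonomy": tax_of.get(mag_id, "") if mag_id else "",
        }
        for method, annots in annots_by_method.items():
            row[f"{method}_terms"] = ";".join(sorted(annots.terms_for(gene, method)))
        rows.append(row)
    return pd.DataFrame(rows)


def write_gene_mapper_tsv(table: pd.DataFrame, handle: IO[str] | None = None) -> str:
    text = table.to_csv(sep="\t", index=False)
    if handle is not None:
        handle.write(text)
    return text


def read_gene_mapper_tsv(source: str | IO[str]) -> pd.DataFrame:
    return pd.read_csv(
        io.StringIO(_read_text(source)), sep="\t", keep_default_na=False
    ).astype({"is_centroid": int})
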