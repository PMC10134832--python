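"""Gene and gene-function abundance in copies per million (CPM).

Reads mapped against the nonredundant gene catalogue yield a per-gene
count per sample.  Two CPM conventions are supported:

``paper_raw``
    cpm_g = c_g * 1e6 / total_reads, the plain reads-per-million scaling
    against the sample's total (quality-controlled) read count.

``length_rescaled`` (default)
    cpm_g = (c_g / L_g) * 1e6 / sum_h (c_h / L_h): counts are first
    divided by the gene's template length so long genes are not
    over-weighted, then closed to one million per sample.

Per-function abundance sums gene CPM over all genes carrying a GO term;
a gene with several terms contributes its full CPM to each of them.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .annotations import AnnotationSet
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

MODES = ("paper_raw", "length_rescaled")


@dataclass
class GeneCounts:
    """Per-sample mapped-read counts against the gene catalogue."""

    sample_id: str
    counts: dict[str, int]
    lengths: dict[str, int]
    total_reads: int | None = None

    def __post_init__(self) -> None:
        neg = [g for g, c in self.counts.items() if c < 0]
        if neg:
            raise ValidationError(f"negative counts for {neg[:3]}")
        bad = [g for g, L in self.lengths.items() if L <= 0]
        if bad:
            raise ValidationError(f"non-positive lengths for {bad[:3]}")
        if self.total_reads is not None and sum(self.counts.values()) > self.total_reads:
            raise ValidationError(
                f"sample {self.sample_id}: mapped counts exceed total_reads"
            )

    def effective_total(self) -> int:
        """Total reads for the paper_raw denominator; falls back to the
        mapped-count sum when the sample total was not supplied."""
        if self.total_reads is not None:
            return self.total_reads
        logger.info(
            "sample %s: total_reads not supplied, using mapped-count sum",
            self.sample_id,
        )
        return sum(self.counts.values())


def read_alignment_counts(
    source: str | IO[str],
    sample_id: str,
    catalogue_genes: Iterable[str] | None = None,
    template_col: str = "#Template",
    length_col: str = "Template_length",
    count_col: str = "readCount",
    total_reads: int | None = None,
) -> GeneCounts:
    """Read a k-mer aligner result TSV (one row per mapped template).

    Column names are header-driven and configurable.  When
    ``catalogue_genes`` is given, genes absent from the file are filled
    in with count 0 (their length is unknown and omitted).  A template
    listed twice is an error.
    """
    if isinstance(source, str):
        text = source if "\n" in source else open(source).read()
    else:
        text = source.read()
    df = pd.read_csv(io.StringIO(text), sep="\t")
    for col in (template_col, length_col, count_col):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} (have {list(df.columns)})")
    counts: dict[str, int] = {}
    lengths: dict[str, int] = {}
    for _, row in df.iterrows():
        gene = str(row[template_col])
        if gene in counts:
            raise ValidationError(f"duplicated template row for gene {gene}")
        counts[gene] = int(row[count_col])
        lengths[gene] = int(row[length_col])
    if catalogue_genes is not None:
        for g in catalogue_genes:
            counts.setdefault(g, 0)
    return GeneCounts(sample_id, counts, lengths, total_reads)


@dataclass
class AbundanceTable:
    """samples x genes CPM matrix with its normalization mode tag."""

    values: pd.DataFrame  # index: sample ids, columns: gene ids
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative CPM values")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def sample_row(self, sample_id: str) -> pd.Series:
        return self.values.loc[sample_id]

    @classmethod
    def from_samples(cls, samples: Iterable[GeneCounts], mode: str) -> "AbundanceTable":
        rows = [cpm_normalize(s, mode).values for s in samples]
        return cls(pd.concat(rows).fillna(0.0), mode)

    def to_wide_tsv(self, handle: IO[str] | None = None) -> str:
        text = self.values.T.rename_axis("gene_id").to_csv(sep="\t")
        if handle is not None:
            handle.write(text)
        return text

    def to_long_tsv(self, handle: IO[str] | None = None) -> str:
        long = (
            self.values.rename_axis("sample_id")
            .reset_index()
            .melt(id_vars="sample_id", var_name="gene_id", value_name="cpm")
        )
        text = long.to_csv(sep="\t", index=False)
        if handle is not None:
            handle.write(text)
        return text


def cpm_normalize(counts: GeneCounts, mode: str = "length_rescaled") -> AbundanceTable:
    """Convert one sample's counts to CPM under the chosen convention."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    genes = sorted(counts.counts)
    c = np.array([counts.counts[g] for g in genes], dtype=float)
    if mode == "paper_raw":
        total = counts.effective_total()
        if total <= 0:
            raise ValueError("paper_raw CPM undefined: total read count is zero")
        cpm = c * 1e6 / total
    else:
        missing = [g for g in genes if counts.counts[g] > 0 and g not in counts.lengths]
        if missing:
            raise ValidationError(f"no template length for {missing[:3]}")
        L = np.array([counts.lengths.get(g, 1) for g in genes], dtype=float)
        rate = c / L
        denom = rate.sum()
        if denom <= 0:
            raise ValueError("length_rescaled CPM undefined: all counts are zero")
        cpm = rate * 1e6 / denom
    df = pd.DataFrame([cpm], index=[counts.sample_id], columns=genes)
    return AbundanceTable(df, mode)


def function_abundance(
    abund: AbundanceTable, annots: AnnotationSet, method: str | None = None
) -> pd.DataFrame:
    """Summed CPM per GO term and sample (terms x samples).

    ``annots`` must be restricted to one method (pass ``method`` to
    select it; with several methods present and none selected, raises).
    A gene annotated with several terms contributes its full CPM to each
    term — no fractional splitting.
    """
    methods = annots.methods()
    if method is None:
        if len(methods) > 1:
            raise ValueError(
                f"annotation set mixes methods {sorted(methods)}; pass method="
            )
        method = next(iter(methods), None)
    gene_terms = {
        g: annots.terms_for(g, method) for g in annots.genes(method)
    }
    all_terms = sorted({t for ts in gene_terms.values() for t in ts})
    out = pd.DataFrame(0.0, index=all_terms, columns=abund.values.index)
    present = set(abund.values.columns)
    for gene, terms in gene_terms.items():
        if gene not in present:
            continue
        col = abund.values[gene]
        for t in terms:
            out.loc[t] += col.values
    out.index.name = "term"
    return out


def annotated_fraction(
    abund: AbundanceTable, annotated_genes: set[str]
) -> pd.Series:
    """Percent of each sample's total CPM carried by annotated genes.

    Samples with zero total abundance are reported as missing (NaN).
    """
    totals = abund.values.sum(axis=1)
    ann_cols = [g for g in abund.values.columns if g in annotated_genes]
    ann = abund.values[ann_cols].sum(axis=1) if ann_cols else pd.Series(
        0.0, index=abund.values.index
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * ann / totals
    pct[totals == 0] = np.nan
    pct.name = "annotated_pct"
    return pct
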