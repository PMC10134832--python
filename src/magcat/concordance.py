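"""Inter-method annotation concordance stratified by information content.

Annotations from two methods are compared per gene after upward
propagation, inside integer IC levels (bin = floor(IC)).  Within a
level, a gene is *concordant* when both methods annotate it there with
at least one identical term, *discordant* when both annotate there with
disjoint term sets, and *unique* to a method when only that method
annotates at the level.  A looser "level_only" mode calls a gene
concordant whenever both methods annotate at the level at all.

Terms missing from the IC table fall in an ``unbinned`` bucket that is
stratified the same way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Iterable, Sequence

import pandas as pd

from .annotations import AnnotationSet
from .errors import ValidationError
from .go_dag import GoDag, ICTable, propagate_up

UNBINNED = "unbinned"

CATEGORIES = ("concordant", "discordant", "unique_a", "unique_b")


def _bin_of(term: str, ic: ICTable) -> Hashable:
    v = ic.get(term)
    return UNBINNED if v is None else math.floor(v)


def _binned_terms(
    annots: AnnotationSet, gene: str, method: str | None, ic: ICTable, dag: GoDag
) -> dict[Hashable, set[str]]:
    closed = propagate_up(dag, annots.terms_for(gene, method), on_missing="drop")
    out: dict[Hashable, set[str]] = {}
    for t in closed:
        out.setdefault(_bin_of(t, ic), set()).add(t)
    return out


def ic_histogram(
    annots: AnnotationSet,
    ic: ICTable,
    dag: GoDag,
    method: str | None = None,
) -> pd.DataFrame:
    """Tally annotations per integer IC level after upward propagation.

    Because the level unit is ambiguous (a gene may hit a level through
    several terms), both tallies are emitted: ``gene_term_pairs`` counts
    (gene, term) pairs in the level, ``genes`` counts distinct genes.
    """
    pair_counts: dict[Hashable, int] = {}
    gene_counts: dict[Hashable, set[str]] = {}
    for gene in annots.genes(method):
        for b, terms in _binned_terms(annots, gene, method, ic, dag).items():
            pair_counts[b] = pair_counts.get(b, 0) + len(terms)
            gene_counts.setdefault(b, set()).add(gene)
    bins = sorted(pair_counts, key=lambda b: (b == UNBINNED, b if b != UNBINNED else 0))
    return pd.DataFrame(
        {
            "bin": bins,
            "gene_term_pairs": [pair_counts[b] for b in bins],
            "genes": [len(gene_counts[b]) for b in bins],
        }
    )


@dataclass
class ConcordanceResult:
    """Per-IC-level counts of the four agreement categories."""

    label_a: str
    label_b: str
    bins: dict[Hashable, dict[str, int]] = field(default_factory=dict)
    mode: str = "term_overlap"

    def _slot(self, b: Hashable) -> dict[str, int]:
        return self.bins.setdefault(b, dict.fromkeys(CATEGORIES, 0))

    def bin_total(self, b: Hashable) -> int:
        return sum(self.bins.get(b, {}).values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for b in sorted(self.bins, key=lambda x: (x == UNBINNED, x if x != UNBINNED else 0)):
            total = self.bin_total(b)
            for cat in CATEGORIES:
                count = self.bins[b][cat]
                rows.append(
                    {
                        "bin": b,
                        "category": cat,
                        "count": count,
                        "percent": 100.0 * count / total if total else float("nan"),
                    }
                )
        return pd.DataFrame(rows)

    def concordant_fraction(self, b: Hashable) -> float:
        total = self.bin_total(b)
        if total == 0:
            raise ValueError(f"no genes in bin {b!r}")
        return self.bins[b]["concordant"] / total


def stratify_concordance(
    a: AnnotationSet,
    b: AnnotationSet,
    ic: ICTable,
    dag: GoDag,
    labels: tuple[str, str] = ("a", "b"),
    mode: str = "term_overlap",
    method_a: str | None = None,
    method_b: str | None = None,
) -> ConcordanceResult:
    """Stratify two methods' gene annotations by IC level.

    Both sets are propagated upward (idempotent if already closed) and
    must live on the same GO branch.  For each gene and each level
    occupied by either method, exactly one category is counted, so the
    four categories partition each level's gene universe.
    """
    if mode not in ("term_overlap", "level_only"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_same_branch(a, b, dag, method_a, method_b)
    result = ConcordanceResult(labels[0], labels[1], mode=mode)
    for gene in a.genes(method_a) | b.genes(method_b):
        bins_a = _binned_terms(a, gene, method_a, ic, dag)
        bins_b = _binned_terms(b, gene, method_b, ic, dag)
        for level in bins_a.keys() | bins_b.keys():
            ta, tb = bins_a.get(level), bins_b.get(level)
            slot = result._slot(level)
            if ta and tb:
                if mode == "level_only" or ta & tb:
                    slot["concordant"] += 1
                else:
                    slot["discordant"] += 1
            elif ta:
                slot["unique_a"] += 1
            else:
                slot["unique_b"] += 1
    return result


def _check_same_branch(
    a: AnnotationSet,
    b: AnnotationSet,
    dag: GoDag,
    method_a: str | None,
    method_b: str | None,
) -> None:
    def branches(annots: AnnotationSet, method: str | None) -> set[str]:
        return {
            dag[t].namespace
            for g in annots.genes(method)
            for t in annots.terms_for(g, method)
            if t in dag
        }

    ba, bb = branches(a, method_a), branches(b, method_b)
    if ba and bb and ba != bb:
        raise ValidationError(
            f"GO branch mismatch between annotation sets: {sorted(ba)} vs {sorted(bb)}"
        )


@dataclass
class VennCounts:
    """Exact region cardinalities of a 2- or 3-way set comparison.

    Regions are keyed by the frozenset of labels whose sets contain the
    region's elements (and no others); regions are disjoint and sum to
    the union's size.
    """

    labels: tuple[str, ...]
    regions: dict[frozenset, int]

    def only(self, *labels: str) -> int:
        return self.regions[frozenset(labels)]

    def set_size(self, label: str) -> int:
        """Reconstruct an input set's size by inclusion of its regions."""
        return sum(c for key, c in self.regions.items() if label in key)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(sorted(key)), "count": count}
            for key, count in sorted(
                self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows)


def annotation_venn(
    sets: Sequence[Iterable[str]], labels: Sequence[str]
) -> VennCounts:
    """Region counts for 2 or 3 gene-id sets (3 or 7 regions)."""
    if len(sets) != len(labels):
        raise ValueError("one label per set required")
    if len(sets) not in (2, 3):
        raise ValueError(f"only 2- or 3-way comparisons supported, got {len(sets)}")
    named = {lab: set(s) for lab, s in zip(labels, sets)}
    regions: dict[frozenset, int] = {}
    for r in range(1, len(named) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(named[l] for l in combo))
            outside = set.union(
                set(), *(named[l] for l in named if l not in combo)
            )
            regions[frozenset(combo)] = len(inside - outside)
    return VennCounts(tuple(labels), regions)
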