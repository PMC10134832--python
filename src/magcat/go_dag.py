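"""Gene Ontology DAG: parsing, upward propagation, information content.

The ontology is modelled as a directed acyclic graph of terms connected by
``is_a`` child-parent edges only.  Annotation specificity is quantified by
Shannon information content, IC(t) = -log2(n_t / n), where ``n_t`` is the
number of proteins annotated with term ``t`` (after upward propagation)
in a reference corpus of ``n`` annotated proteins: frequently used terms
are general (low IC), rare terms are specific (high IC).

"Informative" terms are the maximally specific, well-populated terms: a
term is informative when it annotates strictly more than ``k`` proteins
while every proper descendant annotates strictly fewer than ``k``
(default k = 2000).  The informative set is always an antichain of the
ancestor partial order.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

GO_ACCESSION_RE = re.compile(r"^GO:\d{7}$")

NAMESPACES = frozenset(
    {"molecular_function", "biological_process", "cellular_component"}
)


@dataclass(frozen=True)
class GoTerm:
    """A single ontology term with its direct ``is_a`` parents."""

    id: str
    name: str
    namespace: str
    parents: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not GO_ACCESSION_RE.match(self.id):
            raise ValidationError(f"not a GO accession: {self.id!r}")
        if self.namespace not in NAMESPACES:
            raise ValidationError(f"unknown namespace: {self.namespace!r}")
        if self.id in self.parents:
            raise ValidationError(f"term {self.id} is its own parent")


class GoDag:
    """Immutable view of the ontology restricted to ``is_a`` edges.

    Parameters
    ----------
    terms
        Terms keyed by accession.  Every parent referenced must itself be
        a key; the edge relation must be acyclic.
    """

    def __init__(self, terms: Mapping[str, GoTerm]):
        self._terms = dict(terms)
        for t in self._terms.values():
            missing = t.parents - self._terms.keys()
            if missing:
                raise ValidationError(
                    f"term {t.id} references unknown parent(s): {sorted(missing)}"
                )
        self._check_acyclic()
        self._children: dict[str, set[str]] = {tid: set() for tid in self._terms}
        for t in self._terms.values():
            for p in t.parents:
                self._children[p].add(t.id)
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._terms)
        for t in self._terms.values():
            g.add_edges_from((t.id, p) for p in t.parents)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise ValidationError(f"cyclic is_a relation involving {cycle[0][0]}")

    # -- container protocol -------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self):
        return iter(self._terms)

    def __getitem__(self, term_id: str) -> GoTerm:
        return self._terms[term_id]

    def __eq__(self, other) -> bool:
        return isinstance(other, GoDag) and self._terms == other._terms

    @property
    def terms(self) -> Mapping[str, GoTerm]:
        return self._terms

    def n_edges(self) -> int:
        return sum(len(t.parents) for t in self._terms.values())

    def parents(self, term_id: str) -> frozenset[str]:
        return self._terms[term_id].parents

    def children(self, term_id: str) -> frozenset[str]:
        return frozenset(self._children[term_id])

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All proper ancestors of ``term_id`` via ``is_a``."""
        cached = self._ancestor_cache.get(term_id)
        if cached is not None:
            return cached
        out: set[str] = set()
        frontier = list(self._terms[term_id].parents)
        while frontier:
            cur = frontier.pop()
            if cur in out:
                continue
            out.add(cur)
            frontier.extend(self._terms[cur].parents)
        result = frozenset(out)
        self._ancestor_cache[term_id] = result
        return result

    def descendants(self, term_id: str) -> frozenset[str]:
        """All proper descendants of ``term_id`` via ``is_a``."""
        out: set[str] = set()
        frontier = list(self._children[term_id])
        while frontier:
            cur = frontier.pop()
            if cur in out:
                continue
            out.add(cur)
            frontier.extend(self._children[cur])
        return frozenset(out)


def parse_obo(source: str | IO[str], namespaces: Iterable[str] | None = None) -> GoDag:
    """Parse an OBO 1.2/1.4 document into a :class:`GoDag`.

    Only ``is_a`` relations are kept; ``part_of`` and other relationship
    tags are ignored.  Obsolete terms are dropped.  References to parents
    that are absent from the document (or removed by the namespace filter)
    are pruned with a logged warning.

    Parameters
    ----------
    source
        OBO text, a path to an OBO file, or an open text handle.
    namespaces
        Restrict the DAG to these branches (default: keep all three).
    """
    if isinstance(source, str):
        if "\n" in source or "[Term]" in source:
            handle: IO[str] = io.StringIO(source)
        else:
            handle = open(source)
    else:
        handle = source
    try:
        graph = obonet.read_obo(handle, ignore_obsolete=True)
    except KeyError as exc:
        raise FormatError(f"malformed OBO stanza: missing tag {exc}") from exc
    finally:
        if isinstance(source, str):
            handle.close()

    keep = set(NAMESPACES if namespaces is None else namespaces)
    unknown = keep - NAMESPACES
    if unknown:
        raise ValueError(f"unknown namespace(s): {sorted(unknown)}")

    selected: dict[str, dict] = {}
    for node, data in graph.nodes(data=True):
        if "name" not in data:
            # node materialised only by a dangling is_a reference
            continue
        if data.get("namespace", "molecular_function") in keep:
            selected[node] = data

    terms: dict[str, GoTerm] = {}
    for node, data in selected.items():
        parents = set()
        for ref in data.get("is_a", []):
            if ref in selected:
                parents.add(ref)
            else:
                logger.warning("pruning dangling is_a %s -> %s", node, ref)
        terms[node] = GoTerm(
            id=node,
            name=data["name"],
            namespace=data.get("namespace", "molecular_function"),
            parents=frozenset(parents),
        )
    return GoDag(terms)


def write_obo(dag: GoDag, handle: IO[str] | None = None) -> str:
    """Serialize a DAG back to OBO text (``[Term]`` stanzas, is_a only)."""
    buf = io.StringIO()
    buf.write("format-version: 1.2\nontology: magcat-toy\n")
    for tid in sorted(dag):
        t = dag[tid]
        buf.write(f"\n[Term]\nid: {t.id}\nname: {t.name}\nnamespace: {t.namespace}\n")
        for p in sorted(t.parents):
            buf.write(f"is_a: {p} ! {dag[p].name}\n")
    text = buf.getvalue()
    if handle is not None:
        handle.write(text)
    return text


def propagate_up(
    dag: GoDag, terms: Iterable[str], on_missing: str = "error"
) -> set[str]:
    """Close a term set upward: the input plus all ``is_a`` ancestors.

    Idempotent and monotone.  ``on_missing`` controls ids absent from the
    DAG: ``"error"`` (default) raises, ``"drop"`` skips with a warning.
    """
    if on_missing not in ("error", "drop"):
        raise ValueError(f"on_missing must be 'error' or 'drop', got {on_missing!r}")
    out: set[str] = set()
    for t in terms:
        if t not in dag:
            if on_missing == "error":
                raise KeyError(f"term not in DAG: {t}")
            logger.warning("dropping unknown term %s", t)
            continue
        out.add(t)
        out |= dag.ancestors(t)
    return out


def information_content(n_i: int, n: int) -> float:
    """Shannon information content, -log2(n_i / n), in bits.

    ``n_i`` is the number of proteins annotated with the term (after
    upward propagation) and ``n`` the corpus size.
    """
    if n <= 0 or n_i <= 0:
        raise ValueError(f"counts must be positive (n_i={n_i}, n={n})")
    if n_i > n:
        raise ValueError(f"term count exceeds corpus size ({n_i} > {n})")
    return -math.log2(n_i / n)


@dataclass
class ICTable:
    """Per-term information content, optionally with the underlying counts.

    Either computed from a propagated annotation-count table via
    :meth:`from_counts`, or loaded from a precomputed two-column TSV via
    :meth:`from_tsv` (in which case ``counts``/``n`` are unavailable).
    """

    ic: dict[str, float]
    n: int | None = None
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [t for t, v in self.ic.items() if v < 0]
        if bad:
            raise ValidationError(f"negative IC for {bad[:3]}")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], n: int) -> "ICTable":
        ic = {t: information_content(c, n) for t, c in counts.items() if c > 0}
        return cls(ic=ic, n=n, counts=dict(counts))

    @classmethod
    def from_tsv(cls, source: str | IO[str]) -> "ICTable":
        """Read a headerless two-column TSV of (GO id, IC bits)."""
        ic: dict[str, float] = {}
        for line_no, line in enumerate(_iter_lines(source), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"IC table line {line_no}: expected 2 columns")
            ic[parts[0]] = float(parts[1])
        return cls(ic=ic)

    def to_tsv(self, handle: IO[str] | None = None) -> str:
        text = "".join(f"{t}\t{v!r}\n" for t, v in sorted(self.ic.items()))
        if handle is not None:
            handle.write(text)
        return text

    def get(self, term: str) -> float | None:
        return self.ic.get(term)


def _iter_lines(source: str | IO[str]):
    if isinstance(source, str):
        if "\n" in source or "\t" in source:
            yield from io.StringIO(source)
        else:
            with open(source) as fh:
                yield from fh
    else:
        yield from source


def annotation_counts(
    dag: GoDag, term_sets: Iterable[Iterable[str]]
) -> tuple[dict[str, int], int]:
    """Propagated annotation counts over a corpus of per-protein term sets.

    Each protein contributes one count to every term in the upward
    closure of its annotation set.  Returns ``(counts, n)`` with ``n``
    the number of proteins carrying at least one in-DAG term.
    """
    counts: dict[str, int] = {}
    n = 0
    for terms in term_sets:
        closed = propagate_up(dag, terms, on_missing="drop")
        if not closed:
            continue
        n += 1
        for t in closed:
            counts[t] = counts.get(t, 0) + 1
    return counts, n


@dataclass(frozen=True)
class InformativeConfig:
    """Protein-count threshold for informative-term selection."""

    k: int = 2000

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")


def _validate_propagated(dag: GoDag, counts: Mapping[str, int]) -> None:
    for tid, c in counts.items():
        if tid not in dag:
            continue
        for p in dag.parents(tid):
            if counts.get(p, 0) < c:
                raise ValidationError(
                    f"counts not propagated: child {tid} ({c}) exceeds "
                    f"parent {p} ({counts.get(p, 0)})"
                )


def informative_terms(
    dag: GoDag,
    counts: Mapping[str, int],
    cfg: InformativeConfig = InformativeConfig(),
) -> set[str]:
    """Select terms with count > k whose every proper descendant has count < k.

    ``counts`` must already be upward-propagated (validated: any child
    exceeding its parent raises).  A term absent from ``counts`` is
    treated as count 0.  Counts exactly equal to ``k`` satisfy neither
    strict inequality.  The result is an antichain.
    """
    _validate_propagated(dag, counts)
    k = cfg.k
    out: set[str] = set()
    for tid in dag:
        if counts.get(tid, 0) <= k:
            continue
        if all(counts.get(d, 0) < k for d in dag.descendants(tid)):
            out.add(tid)
    return out


def read_counts_tsv(source: str | IO[str]) -> dict[str, int]:
    """Read a headerless two-column TSV of (GO id, propagated count)."""
    counts: dict[str, int] = {}
    for line_no, line in enumerate(_iter_lines(source), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"counts table line {line_no}: expected 2 columns")
        counts[parts[0]] = int(parts[1])
    return counts
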