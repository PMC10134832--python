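"""Reference-free pangenomes from nearly complete MAGs.

For every species with at least ``min_mags`` nearly complete MAGs
(>= 90% completeness, < 5% contamination), a boolean presence matrix of
gene clusters over the species' MAGs is built.  A cluster present in at
least ``core_fraction`` (default 90%) of the MAGs is *core* — the
inclusive threshold deliberately absorbs MAG incompleteness — and
*accessory* otherwise.  Core and accessory together form the species
pangenome.

An accessory cluster is *shared* when any other species' pangenome
(core or accessory; a strict accessory-vs-accessory mode is available)
also contains it, and *unique* otherwise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalogue import GeneCatalogue
from .errors import ValidationError
from .mag_integration import MagFilterConfig, MagRecord, filter_near_complete


@dataclass(frozen=True)
class PangenomeConfig:
    min_mags: int = 10
    core_fraction: float = 0.90
    mag_filter: MagFilterConfig = field(default_factory=MagFilterConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.core_fraction <= 1.0:
            raise ValueError(f"core_fraction outside (0,1]: {self.core_fraction}")
        if self.min_mags < 1:
            raise ValueError(f"min_mags must be >= 1, got {self.min_mags}")


@dataclass
class PresenceMatrix:
    """Boolean clusters x MAGs matrix for one species.

    A cell is true when the cluster has at least one member gene binned
    into that MAG.  Rows with no true cell are excluded: the matrix
    covers exactly the clusters observed in >= 1 MAG of the species.
    """

    species: str
    values: pd.DataFrame  # index: cluster ids, columns: MAG ids, dtype bool

    def __post_init__(self) -> None:
        if self.values.size and not self.values.any(axis=1).all():
            raise ValidationError(
                f"presence matrix for {self.species} has an all-false row"
            )

    @property
    def n_mags(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, handle: IO[str] | None = None) -> str:
        text = (
            self.values.astype(int).rename_axis("cluster_id").to_csv(sep="\t")
        )
        if handle is not None:
            handle.write(text)
        return text


@dataclass
class Pangenome:
    species: str
    core: set[str]
    accessory: set[str]
    n_mags: int

    def __post_init__(self) -> None:
        overlap = self.core & self.accessory
        if overlap:
            raise ValidationError(f"clusters both core and accessory: {sorted(overlap)[:3]}")

    @property
    def clusters(self) -> set[str]:
        return self.core | self.accessory

    @property
    def size(self) -> int:
        return len(self.core) + len(self.accessory)


def select_pangenome_species(
    mags: Iterable[MagRecord], cfg: PangenomeConfig = PangenomeConfig()
) -> dict[str, list[MagRecord]]:
    """Species with >= min_mags nearly complete MAGs, with those MAGs.

    MAGs with an unassigned species rank never enter a pangenome.
    """
    near_complete = filter_near_complete(mags, cfg.mag_filter)
    by_species: dict[str, list[MagRecord]] = {}
    for m in near_complete:
        sp = m.taxonomy.species
        if sp:
            by_species.setdefault(sp, []).append(m)
    return {
        sp: sorted(ms, key=lambda m: m.mag_id)
        for sp, ms in sorted(by_species.items())
        if len(ms) >= cfg.min_mags
    }


def build_presence_matrix(
    species: str,
    species_mags: Sequence[MagRecord],
    cat: GeneCatalogue,
    gene2mag: Mapping[str, str | None],
) -> PresenceMatrix:
    """Materialize the cluster-by-MAG presence relation for one species."""
    mag_ids = [m.mag_id for m in species_mags]
    mag_pos = {mid: i for i, mid in enumerate(mag_ids)}
    present: dict[str, set[int]] = {}
    for gene, mag_id in gene2mag.items():
        if mag_id not in mag_pos:
            continue
        cid = cat.cluster_of(gene)
        if cid is not None:
            present.setdefault(cid, set()).add(mag_pos[mag_id])
    cluster_ids = sorted(present)
    data = np.zeros((len(cluster_ids), len(mag_ids)), dtype=bool)
    for r, cid in enumerate(cluster_ids):
        for c in present[cid]:
            data[r, c] = True
    return PresenceMatrix(
        species, pd.DataFrame(data, index=cluster_ids, columns=mag_ids)
    )


def classify_core_accessory(
    pm: PresenceMatrix, cfg: PangenomeConfig = PangenomeConfig()
) -> Pangenome:
    """Split observed clusters into core (>= core_fraction of MAGs) and
    accessory (< core_fraction).  The denominator is the species'
    qualifying MAG count, i.e. the matrix's column count."""
    if pm.n_mags < cfg.min_mags:
        raise ValidationError(
            f"{pm.species}: only {pm.n_mags} MAGs, need >= {cfg.min_mags}"
        )
    frac = pm.values.sum(axis=1) / pm.n_mags
    core = set(frac.index[frac >= cfg.core_fraction])
    accessory = set(frac.index) - core
    return Pangenome(pm.species, core, accessory, pm.n_mags)


def shared_unique_accessory(
    pangenomes: Sequence[Pangenome], mode: str = "pangenome"
) -> pd.DataFrame:
    """Per-species shared vs unique accessory counts.

    ``mode="pangenome"`` (default) calls an accessory cluster shared
    when it occurs anywhere — core or accessory — in another species;
    ``mode="accessory_only"`` requires it to be accessory elsewhere too.
    shared + unique equals the species' accessory size.
    """
    if mode not in ("pangenome", "accessory_only"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for pg in pangenomes:
        others: set[str] = set()
        for other in pangenomes:
            if other.species == pg.species:
                continue
            others |= other.clusters if mode == "pangenome" else other.accessory
        shared = len(pg.accessory & others)
        rows.append(
            {
                "species": pg.species,
                "accessory": len(pg.accessory),
                "shared": shared,
                "unique": len(pg.accessory) - shared,
            }
        )
    return pd.DataFrame(rows)


def pangenome_summary(
    pangenomes: Sequence[Pangenome],
    annotated_clusters_by_method: Mapping[str, set[str]] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-species size table plus Pearson r(pangenome size, MAG count).

    For each annotation method (a set of informative-annotated cluster
    ids), the table reports how many core and accessory clusters carry a
    known function.  The correlation is NaN when fewer than 3 pangenomes
    are given or either variable has zero variance.
    """
    annotated_clusters_by_method = annotated_clusters_by_method or {}
    rows = []
    for pg in pangenomes:
        row = {
            "species": pg.species,
            "n_mags": pg.n_mags,
            "core": len(pg.core),
            "accessory": len(pg.accessory),
            "pangenome": pg.size,
        }
        for method, annotated in annotated_clusters_by_method.items():
            row[f"{method}_core_known"] = len(pg.core & annotated)
            row[f"{method}_accessory_known"] = len(pg.accessory & annotated)
        rows.append(row)
    df = pd.DataFrame(rows)
    sizes = df["pangenome"].to_numpy(dtype=float)
    n_mags = df["n_mags"].to_numpy(dtype=float)
    if len(df) < 3 or np.std(sizes) == 0 or np.std(n_mags) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(sizes, n_mags).statistic)
    return df, r


def write_membership_tsv(
    pangenomes: Sequence[Pangenome],
    shared_table: pd.DataFrame | None = None,
    handle: IO[str] | None = None,
    mode: str = "pangenome",
) -> str:
    """Pangenome membership TSV: species, cluster, core|accessory,
    shared|unique (sharing status blank for core clusters)."""
    shared_of: dict[str, set[str]] = {}
    if shared_table is not None or len(pangenomes) > 1:
        for pg in pangenomes:
            others: set[str] = set()
            for other in pangenomes:
                if other.species != pg.species:
                    others |= other.clusters if mode == "pangenome" else other.accessory
            shared_of[pg.species] = pg.accessory & others
    buf = io.StringIO()
    buf.write("species\tcluster_id\tpartition\tsharing\n")
    for pg in pangenomes:
        for cid in sorted(pg.core):
            buf.write(f"{pg.species}\t{cid}\tcore\t\n")
        for cid in sorted(pg.accessory):
            status = "shared" if cid in shared_of.get(pg.species, set()) else "unique"
            buf.write(f"{pg.species}\t{cid}\taccessory\t{status}\n")
    text = buf.getvalue()
    if handle is not None:
        handle.write(text)
    return text
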