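"""Synthetic fixture bundles with planted ground truth.

The generator emulates the statistical structure of the outputs that an
assembly-binning-annotation toolchain would produce for an infant-gut
style metagenome survey, at desk scale:

* a 20-term toy molecular-function ontology with planted propagated
  annotation counts, chosen so the informative-term antichain is known
  in advance and all annotation leaves share one IC level;
* a community of species, each with a planted core and accessory gene
  cluster pool (some accessory clusters shared pairwise between
  species), realized as MAGs with per-gene dropout and optional
  foreign-cluster contamination;
* a nonredundant gene catalogue over all realized genes, written in the
  greedy-clustering ``.clstr`` dialect;
* two centroid-level annotation channels — a score-carrying
  structure-based table and an orthology table with GO ids and free
  text — generated from each cluster's true function with a tunable
  inter-method agreement probability;
* per-sample read-count tables drawn length-proportionally (no read
  simulation: alignment is upstream of this package), optionally
  adjusted so annotated genes carry an exact planted share of the
  sample's counts.

Accessory presence is planted *below* the core threshold by
construction (the number of carrying MAGs is drawn under 90% of the
species' MAGs), so with zero dropout and zero contamination the
core/accessory partition is recoverable exactly.  Core presence is
Bernoulli(1 - dropout) per MAG, so core recovery under dropout follows
a binomial tail law that parameter-recovery tests can check.

Everything is driven by one seeded generator: a fixed seed yields a
byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, asdict
from fractions import Fraction

import numpy as np

from .abundance import GeneCounts
from .annotations import AnnotationRecord, AnnotationSet
from .catalogue import GeneCatalogue, GeneCluster, GeneRecord
from .errors import ValidationError
from .go_dag import GoDag, GoTerm, ICTable, write_obo
from .mag_integration import MagRecord, TaxonomyLabel

# ---------------------------------------------------------------------------
# Toy ontology
# ---------------------------------------------------------------------------

#: (id, name, parents, planted propagated protein count)
_TOY_TERMS: tuple[tuple[str, str, tuple[str, ...], int], ...] = (
    ("GO:0003674", "molecular_function", (), 100000),
    ("GO:0000100", "binding", ("GO:0003674",), 50000),
    ("GO:0000102", "RNA binding", ("GO:0000100",), 1100),
    ("GO:0000110", "ATP binding", ("GO:0000100",), 3000),
    ("GO:0000111", "zinc ion binding", ("GO:0000100",), 700),
    ("GO:0000112", "DNA binding", ("GO:0000100",), 2500),
    ("GO:0000113", "single-stranded DNA binding", ("GO:0000112",), 450),
    ("GO:0000200", "catalytic activity", ("GO:0003674",), 30000),
    ("GO:0000210", "hydrolase activity", ("GO:0000200",), 8000),
    ("GO:0000211", "peptidase activity", ("GO:0000210",), 2200),
    ("GO:0000212", "metallopeptidase activity", ("GO:0000211",), 600),
    ("GO:0000213", "serine-type peptidase activity", ("GO:0000211",), 500),
    ("GO:0000214", "cysteine-type peptidase activity", ("GO:0000211",), 300),
    ("GO:0000220", "transferase activity", ("GO:0000200",), 1900),
    ("GO:0000221", "kinase activity", ("GO:0000220",), 420),
    ("GO:0000300", "transporter activity", ("GO:0003674",), 2100),
    ("GO:0000301", "ion transmembrane transporter activity", ("GO:0000300",), 520),
    ("GO:0000302", "carbohydrate transporter activity", ("GO:0000300",), 610),
    ("GO:0000400", "structural molecule activity", ("GO:0003674",), 1200),
    ("GO:0000401", "structural constituent of ribosome", ("GO:0000400",), 760),
)

TOY_CORPUS_SIZE = 100000

#: terms with count > 2000 whose every descendant has count < 2000
TOY_INFORMATIVE = frozenset(
    {"GO:0000110", "GO:0000112", "GO:0000211", "GO:0000300"}
)

#: specific leaves used as "true functions"; all have IC in [7, 8)
TOY_ANNOTATION_LEAVES = (
    "GO:0000111",
    "GO:0000113",
    "GO:0000212",
    "GO:0000213",
    "GO:0000221",
    "GO:0000301",
    "GO:0000302",
    "GO:0000401",
)

TOY_LEAF_IC_BIN = 7


def toy_ontology() -> tuple[GoDag, dict[str, int], ICTable]:
    """The fixed 20-term molecular-function toy ontology.

    Returns the DAG, the planted propagated counts, and the IC table
    computed from them over a corpus of 100,000 proteins.
    """
    terms = {
        tid: GoTerm(tid, name, "molecular_function", frozenset(parents))
        for tid, name, parents, _ in _TOY_TERMS
    }
    counts = {tid: c for tid, _, _, c in _TOY_TERMS}
    dag = GoDag(terms)
    return dag, counts, ICTable.from_counts(counts, TOY_CORPUS_SIZE)


# ---------------------------------------------------------------------------
# Configuration and outputs
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic community.

    Defaults mirror the regime the analyses are designed for: a handful
    of species with >= 10 nearly complete MAGs each, 5% per-gene MAG
    dropout, ~2% contamination, near-exhaustive structure-based
    annotation coverage versus sparse orthology GO coverage with richer
    free-text coverage, and 70% inter-method agreement.
    """

    seed: int
    n_species: int = 4
    mags_per_species: tuple[int, int] = (10, 14)
    core_pool: int = 60
    accessory_pool: int = 120
    shared_accessory_fraction: float = 0.2
    dropout: float = 0.05
    contamination_rate: float = 0.02
    accessory_prevalence: tuple[float, float] = (0.1, 0.7)
    n_samples: int = 6
    n_unbinned_clusters: int = 10
    genes_per_contig: int = 4
    mean_depth: float = 10.0
    gene_length_range: tuple[int, int] = (300, 1500)
    p_annotate_structure: float = 0.99
    p_annotate_orthology: float = 0.12
    p_description: float = 0.72
    agreement_p: float = 0.7
    p_subthreshold_extra: float = 0.15
    annotated_cpm_fraction: float | None = None

    def __post_init__(self) -> None:
        probs = {
            "shared_accessory_fraction": self.shared_accessory_fraction,
            "dropout": self.dropout,
            "contamination_rate": self.contamination_rate,
            "p_annotate_structure": self.p_annotate_structure,
            "p_annotate_orthology": self.p_annotate_orthology,
            "p_description": self.p_description,
            "agreement_p": self.agreement_p,
            "p_subthreshold_extra": self.p_subthreshold_extra,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} outside [0,1]: {v}")
        lo, hi = self.accessory_prevalence
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError(f"bad accessory_prevalence range: {lo}..{hi}")
        if self.annotated_cpm_fraction is not None and not (
            0.0 < self.annotated_cpm_fraction < 1.0
        ):
            raise ValidationError(
                f"annotated_cpm_fraction outside (0,1): {self.annotated_cpm_fraction}"
            )


@dataclass
class TruthManifest:
    """Planted ground truth; fully determines every downstream oracle."""

    seed: int
    informative_terms: list[str]
    leaf_ic_bin: int
    corpus_size: int
    species: dict[str, dict]           # species label -> {core, accessory, shared}
    mags: dict[str, dict]              # mag id -> realized QC + species
    genes: dict[str, list]             # gene id -> [cluster id, mag id or None]
    annotations: dict[str, dict]       # method -> centroid -> sorted terms
    agreement: dict                    # n_both / n_agree for the two methods
    sample_counts: dict[str, dict]     # sample -> gene -> drawn count
    annotated_count_fraction: dict     # method -> sample -> realized fraction

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))


@dataclass
class FixtureBundle:
    """In-memory counterpart of every emitted fixture file."""

    config: SimulationConfig
    dag: GoDag
    go_counts: dict[str, int]
    ic_table: ICTable
    catalogue: GeneCatalogue
    genes: dict[str, GeneRecord]
    sequences: dict[str, str]
    cluster_lengths: dict[str, int]
    mags: list[MagRecord]
    structure_annotations: AnnotationSet   # above-threshold truth (centroids)
    structure_rows: list[tuple[str, str, float]]  # all emitted rows incl. noise
    orthology_annotations: AnnotationSet   # centroid-level
    counts_by_sample: dict[str, GeneCounts]
    manifest: TruthManifest


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _species_taxonomy(i: int) -> TaxonomyLabel:
    genus = f"Testus{i // 2 + 1}"
    return TaxonomyLabel(
        domain="Bacteria",
        phylum="Testota",
        class_="Testia",
        order="Testales",
        family=f"Testaceae{i // 4 + 1}",
        genus=genus,
        species=f"{genus} sp{i + 1:03d}",
    )


def _force_count_fraction(
    counts: dict[str, int], annotated: set[str], fraction: float
) -> None:
    """Adjust integer counts in place so annotated genes carry exactly
    ``fraction`` of the total.  No-op when the sample has no annotated
    or no unannotated genes."""
    ann = sorted(g for g in counts if g in annotated)
    una = sorted(g for g in counts if g not in annotated)
    if not ann or not una:
        return
    f = Fraction(fraction).limit_denominator(10_000)
    p, q = f.numerator, f.denominator
    d = (q - p) // math.gcd(p, q - p)
    U = sum(counts[g] for g in una)
    pad = (-U) % d
    if pad:
        counts[una[0]] += pad
        U += pad
    target = U * p // (q - p)
    A = sum(counts[g] for g in ann)
    if A == 0:
        counts[ann[0]] = target
        return
    # rescale annotated counts to the exact target sum
    scaled = [counts[g] * target // A for g in ann]
    remainder = target - sum(scaled)
    for i in range(remainder):
        scaled[i % len(scaled)] += 1
    for g, c in zip(ann, scaled):
        counts[g] = c


def simulate_community(cfg: SimulationConfig) -> tuple[FixtureBundle, TruthManifest]:
    """Generate one complete fixture bundle plus its truth manifest."""
    rng = np.random.default_rng(cfg.seed)
    dag, go_counts, ic_table = toy_ontology()
    leaves = list(TOY_ANNOTATION_LEAVES)

    samples = [f"S{i:02d}" for i in range(cfg.n_samples)]
    lo_len, hi_len = cfg.gene_length_range

    # -- planted cluster pools ---------------------------------------------
    # plan entries: {"key", "species": [idx...], "kind", "length", "leaf"}
    plans: list[dict] = []
    for sp in range(cfg.n_species):
        for j in range(cfg.core_pool):
            plans.append(
                {
                    "key": f"sp{sp}_core{j:04d}",
                    "species": [sp],
                    "kind": "core",
                    "length": int(rng.integers(lo_len, hi_len + 1)),
                    "leaf": leaves[int(rng.integers(len(leaves)))],
                }
            )
        for j in range(cfg.accessory_pool):
            plans.append(
                {
                    "key": f"sp{sp}_acc{j:04d}",
                    "species": [sp],
                    "kind": "accessory",
                    "length": int(rng.integers(lo_len, hi_len + 1)),
                    "leaf": leaves[int(rng.integers(len(leaves)))],
                }
            )
    n_shared = 0
    if cfg.n_species >= 2:
        n_shared = round(
            cfg.n_species * cfg.accessory_pool * cfg.shared_accessory_fraction / 2
        )
    for j in range(n_shared):
        pair = rng.choice(cfg.n_species, size=2, replace=False)
        plans.append(
            {
                "key": f"shared{j:04d}",
                "species": sorted(int(x) for x in pair),
                "kind": "accessory",
                "length": int(rng.integers(lo_len, hi_len + 1)),
                "leaf": leaves[int(rng.integers(len(leaves)))],
            }
        )

    by_species: dict[int, list[dict]] = {sp: [] for sp in range(cfg.n_species)}
    for plan in plans:
        for sp in plan["species"]:
            by_species[sp].append(plan)

    # -- MAGs: realized cluster content ------------------------------------
    lo_m, hi_m = cfg.mags_per_species
    mag_plan: list[dict] = []  # {"mag_id","sample","species","clusters",...}
    bins_per_sample = dict.fromkeys(samples, 0)
    mag_cursor = 0
    for sp in range(cfg.n_species):
        m = int(rng.integers(lo_m, hi_m + 1))
        # accessory presence planted strictly below the core threshold
        max_carry = max(1, math.ceil(0.9 * m) - 1)
        acc_carry: dict[str, list[int]] = {}
        for plan in by_species[sp]:
            if plan["kind"] != "accessory":
                continue
            k = int(rng.integers(1, max_carry + 1))
            carriers = sorted(int(x) for x in rng.choice(m, size=k, replace=False))
            acc_carry[plan["key"]] = carriers
        for local in range(m):
            sample = samples[mag_cursor % len(samples)]
            mag_cursor += 1
            bins_per_sample[sample] += 1
            mag_id = f"{sample}_bin{bins_per_sample[sample]}"
            own: list[dict] = []
            core_present = 0
            for plan in by_species[sp]:
                if plan["kind"] == "core":
                    if rng.random() >= cfg.dropout:
                        own.append(plan)
                        core_present += 1
                elif local in acc_carry[plan["key"]]:
                    own.append(plan)
            foreign: list[dict] = []
            if cfg.contamination_rate > 0 and cfg.n_species >= 2:
                pool = [p for p in plans if sp not in p["species"]]
                n_foreign = int(rng.binomial(len(own), cfg.contamination_rate))
                if n_foreign:
                    idx = rng.choice(len(pool), size=n_foreign, replace=False)
                    foreign = [pool[int(i)] for i in sorted(idx)]
            completeness = 100.0 * core_present / cfg.core_pool
            contamination = 100.0 * len(foreign) / max(len(own), 1)
            mag_plan.append(
                {
                    "mag_id": mag_id,
                    "sample": sample,
                    "species": sp,
                    "clusters": own + foreign,
                    "n_foreign": len(foreign),
                    "completeness": completeness,
                    "contamination": min(contamination, 100.0),
                }
            )

    # -- genes, contigs, clusters ------------------------------------------
    cluster_members: dict[str, list[str]] = {}
    cluster_order: list[str] = []
    genes: dict[str, GeneRecord] = {}
    gene_home: dict[str, str | None] = {}
    plan_by_key = {p["key"]: p for p in plans}
    mag_contigs: dict[str, set[str]] = {}

    for mp in mag_plan:
        contig_no = 0
        slot = 0
        contigs: set[str] = set()
        for plan in sorted(mp["clusters"], key=lambda p: p["key"]):
            if slot % cfg.genes_per_contig == 0:
                contig_no += 1
            contig = f"{mp['mag_id']}.c{contig_no}"
            contigs.add(contig)
            gene_id = f"{contig}_{slot % cfg.genes_per_contig + 1}"
            slot += 1
            genes[gene_id] = GeneRecord(gene_id, mp["sample"], plan["length"])
            gene_home[gene_id] = mp["mag_id"]
            key = plan["key"]
            if key not in cluster_members:
                cluster_members[key] = []
                cluster_order.append(key)
            cluster_members[key].append(gene_id)
        mag_contigs[mp["mag_id"]] = contigs

    # unbinned singleton clusters per sample
    for sample in samples:
        for j in range(cfg.n_unbinned_clusters):
            contig = f"{sample}_u{j + 1}"
            gene_id = f"{contig}_1"
            length = int(rng.integers(lo_len, hi_len + 1))
            key = f"unb_{sample}_{j:03d}"
            plan_by_key[key] = {"key": key, "kind": "unbinned", "length": length, "leaf": None, "species": []}
            genes[gene_id] = GeneRecord(gene_id, sample, length)
            gene_home[gene_id] = None
            cluster_members[key] = [gene_id]
            cluster_order.append(key)

    clusters: list[GeneCluster] = []
    key_to_cid: dict[str, str] = {}
    cluster_lengths: dict[str, int] = {}
    for idx, key in enumerate(cluster_order):
        cid = f"Cluster_{idx}"
        key_to_cid[key] = cid
        members = cluster_members[key]
        clusters.append(GeneCluster(cid, members[0], frozenset(members)))
        cluster_lengths[cid] = plan_by_key[key]["length"]
    catalogue = GeneCatalogue(clusters)

    # decorative sequences
    alphabet = np.array(list("ACGT"))
    sequences = {
        g: "".join(alphabet[rng.integers(0, 4, size=rec.length)])
        for g, rec in sorted(genes.items())
    }

    # -- MAG records --------------------------------------------------------
    mags = [
        MagRecord(
            mag_id=mp["mag_id"],
            sample_id=mp["sample"],
            contigs=frozenset(mag_contigs[mp["mag_id"]]),
            completeness=round(mp["completeness"], 2),
            contamination=round(mp["contamination"], 2),
            taxonomy=_species_taxonomy(mp["species"]),
        )
        for mp in mag_plan
    ]

    # -- centroid annotations ----------------------------------------------
    structure = AnnotationSet()
    structure_rows: list[tuple[str, str, float]] = []
    orthology = AnnotationSet()
    n_both = 0
    n_agree = 0
    for key in cluster_order:
        plan = plan_by_key[key]
        leaf = plan["leaf"]
        centroid = catalogue.clusters[key_to_cid[key]].centroid
        if leaf is None:
            continue
        has_orth = rng.random() < cfg.p_annotate_orthology
        has_struct = rng.random() < cfg.p_annotate_structure
        agree = rng.random() < cfg.agreement_p
        if has_orth:
            orthology.add(AnnotationRecord(centroid, leaf, 1.0, "eggnog"))
        if has_struct:
            if agree:
                struct_leaf = leaf
            else:
                others = [t for t in leaves if t != leaf]
                struct_leaf = others[int(rng.integers(len(others)))]
            score = round(float(rng.uniform(0.2, 1.0)), 3)
            structure.add(AnnotationRecord(centroid, struct_leaf, score, "deepfri"))
            structure_rows.append((centroid, struct_leaf, score))
            if has_orth:
                n_both += 1
                if struct_leaf == leaf:
                    n_agree += 1
        if rng.random() < cfg.p_subthreshold_extra:
            noise_leaf = leaves[int(rng.integers(len(leaves)))]
            noise_score = round(float(rng.uniform(0.0, 0.199)), 3)
            structure_rows.append((centroid, noise_leaf, noise_score))
        if rng.random() < cfg.p_description:
            orthology.descriptions[centroid] = (
                f"hypothetical protein {key_to_cid[key]}"
            )

    # -- per-sample counts --------------------------------------------------
    # genes whose cluster centroid is structure-annotated, post-propagation
    struct_centroids = structure.genes()
    annotated_genes = {
        g
        for cl in catalogue.clusters.values()
        if cl.centroid in struct_centroids
        for g in cl.members
    }
    counts_by_sample: dict[str, GeneCounts] = {}
    sample_counts_truth: dict[str, dict[str, int]] = {}
    ann_fraction: dict[str, dict[str, float]] = {"deepfri": {}, "eggnog": {}}
    orth_centroids = orthology.genes()
    orth_genes = {
        g
        for cl in catalogue.clusters.values()
        if cl.centroid in orth_centroids
        for g in cl.members
    }
    all_genes = sorted(catalogue.gene_index)
    for sample in samples:
        factor = {
            sp: float(rng.lognormal(0.0, 0.5)) for sp in range(cfg.n_species)
        }
        counts: dict[str, int] = {}
        for g in all_genes:
            rec = genes[g]
            if rec.sample_id != sample:
                continue
            mag_id = gene_home[g]
            sp_factor = 1.0
            if mag_id is not None:
                sp = next(mp["species"] for mp in mag_plan if mp["mag_id"] == mag_id)
                sp_factor = factor[sp]
            lam = cfg.mean_depth * rec.length / 1000.0 * sp_factor
            counts[g] = int(rng.poisson(lam))
        if cfg.annotated_cpm_fraction is not None:
            _force_count_fraction(counts, annotated_genes, cfg.annotated_cpm_fraction)
        full_counts = {g: counts.get(g, 0) for g in all_genes}
        lengths = {g: genes[g].length for g, c in counts.items() if c}
        total = sum(full_counts.values())
        total_reads = int(total * 1.05) + 1
        counts_by_sample[sample] = GeneCounts(
            sample, full_counts, lengths, total_reads
        )
        sample_counts_truth[sample] = {g: c for g, c in counts.items() if c}
        for method, gene_set in (("deepfri", annotated_genes), ("eggnog", orth_genes)):
            ann = sum(c for g, c in full_counts.items() if g in gene_set)
            ann_fraction[method][sample] = ann / total if total else float("nan")

    # -- manifest -----------------------------------------------------------
    species_truth: dict[str, dict] = {}
    for sp in range(cfg.n_species):
        label = _species_taxonomy(sp).species
        core = sorted(
            key_to_cid[p["key"]]
            for p in by_species[sp]
            if p["kind"] == "core" and p["key"] in key_to_cid
        )
        accessory = sorted(
            key_to_cid[p["key"]]
            for p in by_species[sp]
            if p["kind"] == "accessory" and p["key"] in key_to_cid
        )
        shared = sorted(
            key_to_cid[p["key"]]
            for p in by_species[sp]
            if len(p["species"]) > 1 and p["key"] in key_to_cid
        )
        species_truth[label] = {
            "core": core,
            "accessory": accessory,
            "shared_accessory": shared,
        }
    manifest = TruthManifest(
        seed=cfg.seed,
        informative_terms=sorted(TOY_INFORMATIVE),
        leaf_ic_bin=TOY_LEAF_IC_BIN,
        corpus_size=TOY_CORPUS_SIZE,
        species=species_truth,
        mags={
            mp["mag_id"]: {
                "species": _species_taxonomy(mp["species"]).species,
                "completeness": round(mp["completeness"], 2),
                "contamination": round(mp["contamination"], 2),
                "n_foreign_clusters": mp["n_foreign"],
            }
            for mp in mag_plan
        },
        genes={
            g: [catalogue.gene_index[g], gene_home[g]] for g in sorted(genes)
        },
        annotations={
            "deepfri": {
                g: sorted(structure.terms_for(g)) for g in sorted(structure.genes())
            },
            "eggnog": {
                g: sorted(orthology.terms_for(g)) for g in sorted(orthology.genes())
            },
        },
        agreement={"n_both": n_both, "n_agree": n_agree},
        sample_counts=sample_counts_truth,
        annotated_count_fraction=ann_fraction,
    )

    bundle = FixtureBundle(
        config=cfg,
        dag=dag,
        go_counts=go_counts,
        ic_table=ic_table,
        catalogue=catalogue,
        genes=genes,
        sequences=sequences,
        cluster_lengths=cluster_lengths,
        mags=mags,
        structure_annotations=structure,
        structure_rows=structure_rows,
        orthology_annotations=orthology,
        counts_by_sample=counts_by_sample,
        manifest=manifest,
    )
    return bundle, manifest


# ---------------------------------------------------------------------------
# Rendering and writing
# ---------------------------------------------------------------------------


def render_clstr(bundle: FixtureBundle) -> str:
    """Greedy-clustering ``.clstr`` text; the centroid line carries '*'."""
    lines: list[str] = []
    ordered = sorted(
        bundle.catalogue.clusters.values(),
        key=lambda cl: int(cl.cluster_id.rsplit("_", 1)[1]),
    )
    for cl in ordered:
        n = cl.cluster_id.rsplit("_", 1)[1]
        lines.append(f">Cluster {n}")
        members = [cl.centroid] + sorted(cl.members - {cl.centroid})
        for i, g in enumerate(members):
            length = bundle.genes[g].length
            tail = "*" if g == cl.centroid else "at +/96.50%"
            lines.append(f"{i}\t{length}nt, >{g}... {tail}")
    return "\n".join(lines) + "\n"


def render_fasta(bundle: FixtureBundle) -> str:
    out = []
    for g in sorted(bundle.sequences):
        seq = bundle.sequences[g]
        out.append(f">{g}")
        out.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
    return "\n".join(out) + "\n"


def render_bin_membership(bundle: FixtureBundle) -> str:
    lines = ["contig_id\tmag_id"]
    for mag in sorted(bundle.mags, key=lambda m: m.mag_id):
        for contig in sorted(mag.contigs):
            lines.append(f"{contig}\t{mag.mag_id}")
    return "\n".join(lines) + "\n"


def render_checkm(bundle: FixtureBundle) -> str:
    lines = ["Bin Id\tCompleteness\tContamination"]
    for mag in sorted(bundle.mags, key=lambda m: m.mag_id):
        lines.append(f"{mag.mag_id}\t{mag.completeness:.2f}\t{mag.contamination:.2f}")
    return "\n".join(lines) + "\n"


def render_gtdb(bundle: FixtureBundle) -> str:
    lines = ["user_genome\tclassification"]
    for mag in sorted(bundle.mags, key=lambda m: m.mag_id):
        lines.append(f"{mag.mag_id}\t{mag.taxonomy.to_gtdb()}")
    return "\n".join(lines) + "\n"


def render_structure_csv(bundle: FixtureBundle) -> str:
    dag = bundle.dag
    lines = ["gene_id,term,score,term_name"]
    for gene, term, score in bundle.structure_rows:
        lines.append(f"{gene},{term},{score},{dag[term].name}")
    return "\n".join(lines) + "\n"


def render_orthology_tsv(bundle: FixtureBundle) -> str:
    ann = bundle.orthology_annotations
    lines = [
        "# emapper-style annotations",
        "#query\tGOs\teggNOG free text desc.",
    ]
    for gene in sorted(ann.genes() | ann.described_genes()):
        gos = ",".join(sorted(ann.terms_for(gene, "eggnog"))) or "-"
        desc = ann.descriptions.get(gene, "") or "-"
        lines.append(f"{gene}\t{gos}\t{desc}")
    return "\n".join(lines) + "\n"


def render_counts_res(counts: GeneCounts) -> str:
    lines = ["#Template\tTemplate_length\treadCount"]
    for g in sorted(counts.counts):
        c = counts.counts[g]
        if c == 0:
            continue
        lines.append(f"{g}\t{counts.lengths[g]}\t{c}")
    return "\n".join(lines) + "\n"


def render_samples_tsv(bundle: FixtureBundle) -> str:
    lines = ["sample_id\ttotal_reads"]
    for sample in sorted(bundle.counts_by_sample):
        lines.append(f"{sample}\t{bundle.counts_by_sample[sample].total_reads}")
    return "\n".join(lines) + "\n"


FILE_KINDS = (
    "ontology",
    "ic_table",
    "go_counts",
    "fasta",
    "clstr",
    "bins",
    "checkm",
    "gtdb",
    "structure",
    "orthology",
    "counts",
    "samples",
    "truth",
)


def write_fixtures(bundle: FixtureBundle, directory: str) -> dict[str, str]:
    """Write every fixture file plus a SHA-256 checksum manifest.

    Returns a map of file kind to path; the per-sample count tables are
    listed under ``counts/<sample>.res.tsv`` and the kind ``counts``
    points at their directory.
    """
    os.makedirs(directory, exist_ok=True)
    counts_dir = os.path.join(directory, "counts")
    os.makedirs(counts_dir, exist_ok=True)

    files: dict[str, str] = {}

    def put(kind: str, name: str, text: str) -> None:
        path = os.path.join(directory, name)
        with open(path, "w") as fh:
            fh.write(text)
        files[kind] = path

    go_counts_text = "".join(
        f"{t}\t{c}\n" for t, c in sorted(bundle.go_counts.items())
    )
    put("ontology", "ontology.obo", write_obo(bundle.dag))
    put("ic_table", "ic_table.tsv", bundle.ic_table.to_tsv())
    put("go_counts", "go_counts.tsv", go_counts_text)
    put("fasta", "genes.fna", render_fasta(bundle))
    put("clstr", "catalogue.clstr", render_clstr(bundle))
    put("bins", "bins.tsv", render_bin_membership(bundle))
    put("checkm", "checkm.tsv", render_checkm(bundle))
    put("gtdb", "gtdbtk.tsv", render_gtdb(bundle))
    put("structure", "deepfri.csv", render_structure_csv(bundle))
    put("orthology", "eggnog.annotations.tsv", render_orthology_tsv(bundle))
    put("samples", "samples.tsv", render_samples_tsv(bundle))
    put("truth", "truth.json", bundle.manifest.to_json())
    for sample in sorted(bundle.counts_by_sample):
        path = os.path.join(counts_dir, f"{sample}.res.tsv")
        with open(path, "w") as fh:
            fh.write(render_counts_res(bundle.counts_by_sample[sample]))
    files["counts"] = counts_dir

    checks = []
    for root, _, names in sorted(os.walk(directory)):
        for name in sorted(names):
            if name == "SHA256SUMS":
                continue
            path = os.path.join(root, name)
            digest = hashlib.sha256(open(path, "rb").read()).hexdigest()
            rel = os.path.relpath(path, directory)
            checks.append(f"{digest}  {rel}")
    with open(os.path.join(directory, "SHA256SUMS"), "w") as fh:
        fh.write("\n".join(checks) + "\n")
    files["checksums"] = os.path.join(directory, "SHA256SUMS")
    return files
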