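"""MAG quality filtering, gene->MAG mapping, taxonomy integration."""

import pytest

from magcat.annotations import AnnotationRecord, AnnotationSet
from magcat.catalogue import GeneCatalogue, GeneCluster, GeneRecord, parse_clstr
from magcat.errors import ValidationError
from magcat.mag_integration import (
    MagFilterConfig,
    MagRecord,
    TaxonomyLabel,
    build_gene_mapper_table,
    cluster_taxonomy_sharing,
    filter_near_complete,
    map_genes_to_mags,
    read_bin_membership,
    read_gene_mapper_tsv,
    read_mag_metadata,
    write_gene_mapper_tsv,
)

CHECKM = "Bin Id\tCompleteness\tContamination\nS0_bin1\t95.50\t1.20\nS0_bin2\t88.00\t0.50\nS1_bin1\t99.10\t4.90\n"
GTDB = (
    "user_genome\tclassification\n"
    "S0_bin1\td__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;"
    "f__Bacteroidaceae;g__Bacteroides;s__Bacteroides dorei\n"
    "S1_bin1\td__Bacteria;p__Firmicutes;c__Bacilli;o__;f__;g__;s__\n"
)
BINS = "contig_id\tmag_id\nS0_c1\tS0_bin1\nS0_c2\tS0_bin1\nS0_c3\tS0_bin2\nS1_c1\tS1_bin1\n"


def _mag(mag_id="m1", sample="S0", comp=95.0, cont=1.0, species="", contigs=("c1",)):
    tax = TaxonomyLabel(
        domain="Bacteria", phylum="P", class_="C", order="O",
        family="F", genus="G", species=species,
    ) if species else TaxonomyLabel()
    return MagRecord(mag_id, sample, frozenset(contigs), comp, cont, tax)


class TestTaxonomy:
    def test_gtdb_prefixes_stripped(self):
        t = TaxonomyLabel.from_gtdb(
            "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;"
            "f__Bacteroidaceae;g__Bacteroides;s__Bacteroides dorei"
        )
        assert t.species == "Bacteroides dorei"
        assert t.genus == "Bacteroides"
        assert t.domain == "Bacteria"

    def test_empty_rank_blanks_lower_ranks(self):
        t = TaxonomyLabel.from_gtdb("d__Bacteria;p__;c__Bacilli;o__;f__;g__;s__X")
        assert t.phylum == "" and t.class_ == "" and t.species == ""

    def test_round_trip(self):
        s = "d__Bacteria;p__Firmicutes;c__Bacilli;o__;f__;g__;s__"
        assert TaxonomyLabel.from_gtdb(s).to_gtdb() == s


class TestMetadata:
    def test_three_bin_fixture(self):
        mags = read_mag_metadata(CHECKM, GTDB, read_bin_membership(BINS))
        by_id = {m.mag_id: m for m in mags}
        assert len(mags) == 3
        assert by_id["S0_bin1"].completeness == 95.5
        assert by_id["S0_bin1"].taxonomy.species == "Bacteroides dorei"
        assert by_id["S0_bin1"].contigs == {"S0_c1", "S0_c2"}
        assert by_id["S0_bin1"].sample_id == "S0"

    def test_bin_without_taxonomy_gets_empty_label(self):
        mags = read_mag_metadata(CHECKM, GTDB, read_bin_membership(BINS))
        by_id = {m.mag_id: m for m in mags}
        assert by_id["S0_bin2"].taxonomy == TaxonomyLabel()

    def test_bin_without_qc_strict_vs_lenient(self):
        bins = read_bin_membership(BINS + "S9_c1\tS9_bin1\n")
        assert len(read_mag_metadata(CHECKM, GTDB, bins)) == 3
        with pytest.raises(ValidationError, match="S9_bin1"):
            read_mag_metadata(CHECKM, GTDB, bins, strict=True)

    def test_out_of_range_quality_rejected(self):
        bad = "Bin Id\tCompleteness\tContamination\nS0_bin1\t120.0\t1.0\n"
        with pytest.raises(ValidationError):
            read_mag_metadata(bad, None, {"S0_bin1": {"S0_c1"}})


class TestNearCompleteFilter:
    @pytest.mark.parametrize(
        "comp,cont,kept",
        [
            (90.0, 4.9, True),   # both boundaries on the kept side
            (89.9, 4.9, False),  # completeness strict miss
            (90.0, 5.0, False),  # contamination boundary is exclusive
            (100.0, 0.0, True),
        ],
    )
    def test_90_5_boundaries(self, comp, cont, kept):
        mags = [_mag(comp=comp, cont=cont)]
        assert bool(filter_near_complete(mags)) is kept

    def test_empty_input(self):
        assert filter_near_complete([]) == []

    def test_monotone_in_thresholds(self):
        mags = [_mag(f"m{i}", comp=80 + i * 2.0, cont=i * 0.7) for i in range(10)]
        tight = {m.mag_id for m in filter_near_complete(mags, MagFilterConfig(90, 5))}
        loose = {m.mag_id for m in filter_near_complete(mags, MagFilterConfig(85, 7))}
        assert tight <= loose


class TestGeneMapping:
    def test_binned_and_unbinned(self):
        genes = [GeneRecord("S0_c1_1", "S0", 300), GeneRecord("S0_c9_1", "S0", 300)]
        mags = [_mag("S0_bin1", contigs=("S0_c1",))]
        g2m = map_genes_to_mags(genes, mags)
        assert g2m == {"S0_c1_1": "S0_bin1", "S0_c9_1": None}

    def test_contig_claimed_twice_in_one_sample_rejected(self):
        mags = [
            _mag("m1", contigs=("c1",)),
            _mag("m2", contigs=("c1",)),
        ]
        with pytest.raises(ValidationError, match="c1"):
            map_genes_to_mags([], mags)

    def test_same_contig_name_in_different_samples_ok(self):
        mags = [
            _mag("m1", sample="S0", contigs=("c1",)),
            _mag("m2", sample="S1", contigs=("c1",)),
        ]
        genes = [GeneRecord("c1_1", "S1", 100)]
        assert map_genes_to_mags(genes, mags) == {"c1_1": "m2"}

    def test_matches_brute_force_join(self, bundle):
        from magcat.mag_integration import map_genes_to_mags as mapper

        genes = list(bundle.genes.values())[:200]
        g2m = mapper(genes, bundle.mags)
        for g in genes:
            expected = None
            for m in bundle.mags:
                if m.sample_id == g.sample_id and g.contig_id in m.contigs:
                    expected = m.mag_id
            assert g2m[g.gene_id] == expected


class TestTaxonomySharing:
    def _setup(self):
        cat = GeneCatalogue(
            [
                GeneCluster("c0", "A_c1_1", frozenset({"A_c1_1", "B_c1_1"})),
                GeneCluster("c1", "A_c2_1", frozenset({"A_c2_1"})),
                GeneCluster("c2", "X_u1_1", frozenset({"X_u1_1"})),
            ]
        )
        mags = [
            _mag("magA", sample="A", species="G spA", contigs=("A_c1", "A_c2")),
            _mag("magB", sample="B", species="G spB", contigs=("B_c1",)),
        ]
        g2m = {"A_c1_1": "magA", "B_c1_1": "magB", "A_c2_1": "magA", "X_u1_1": None}
        return cat, g2m, mags

    def test_distinct_species_counted(self):
        cat, g2m, mags = self._setup()
        counts = cluster_taxonomy_sharing(cat, g2m, mags, "species")
        assert counts == {"c0": 2, "c1": 1, "c2": 0}

    def test_same_genus_counts_once(self):
        cat, g2m, mags = self._setup()
        counts = cluster_taxonomy_sharing(cat, g2m, mags, "genus")
        assert counts["c0"] == 1

    def test_contaminated_mags_excluded(self):
        cat, g2m, mags = self._setup()
        mags[1] = _mag("magB", sample="B", species="G spB", cont=5.0, contigs=("B_c1",))
        counts = cluster_taxonomy_sharing(cat, g2m, mags, "species")
        assert counts["c0"] == 1

    def test_invalid_rank_rejected(self):
        cat, g2m, mags = self._setup()
        with pytest.raises(ValueError):
            cluster_taxonomy_sharing(cat, g2m, mags, "phylum")

    def test_matches_brute_force_on_synthetic_community(self, bundle):
        g2m = map_genes_to_mags(bundle.genes.values(), bundle.mags)
        counts = cluster_taxonomy_sharing(bundle.catalogue, g2m, bundle.mags, "species")
        mag_by_id = {m.mag_id: m for m in bundle.mags}
        for cid, cl in bundle.catalogue.clusters.items():
            labels = set()
            for g in cl.members:
                mid = g2m[g]
                if mid is None:
                    continue
                m = mag_by_id[mid]
                if m.contamination < 5.0 and m.taxonomy.species:
                    labels.add(m.taxonomy.species)
            assert counts[cid] == len(labels)

    def test_nonzero_count_iff_binned_low_contamination_member(self, bundle):
        g2m = map_genes_to_mags(bundle.genes.values(), bundle.mags)
        counts = cluster_taxonomy_sharing(bundle.catalogue, g2m, bundle.mags, "species")
        qualifying = {
            m.mag_id for m in bundle.mags if m.contamination < 5.0
        }
        touched = {
            bundle.catalogue.gene_index[g]
            for g, mid in g2m.items()
            if mid in qualifying
        }
        assert {cid for cid, c in counts.items() if c >= 1} == touched


class TestGeneMapperTable:
    def test_row_count_and_round_trip(self, bundle):
        g2m = map_genes_to_mags(bundle.genes.values(), bundle.mags)
        annots = {"deepfri": bundle.structure_annotations}
        table = build_gene_mapper_table(bundle.catalogue, g2m, bundle.mags, annots)
        assert len(table) == bundle.catalogue.n_genes
        back = read_gene_mapper_tsv(write_gene_mapper_tsv(table))
        assert back.equals(table)

    def test_annotation_columns_match_independent_join(self, bundle):
        g2m = map_genes_to_mags(bundle.genes.values(), bundle.mags)
        annots = {"deepfri": bundle.structure_annotations}
        table = build_gene_mapper_table(
            bundle.catalogue, g2m, bundle.mags, annots
        ).set_index("gene_id")
        for g in list(bundle.catalogue.gene_index)[:100]:
            expected = ";".join(
                sorted(bundle.structure_annotations.terms_for(g, "deepfri"))
            )
            assert table.loc[g, "deepfri_terms"] == expected
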