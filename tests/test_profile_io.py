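"""Readers and writers for profile, annotation and matrix formats."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from paneval import (
    AnnotationConflictError,
    DuplicateGeneError,
    FormatError,
    GeneId,
    GenomeMap,
    PanProfile,
    UnknownGenomeError,
    UsageError,
    classify_clusters,
    read_cog_table,
    read_generic_clusters,
    read_genome_map,
    read_orthofinder_tsv,
    read_roary_csv,
    write_generic_clusters,
    write_presence_absence,
)
from paneval.profile_io import ROARY_META_COLUMNS

from conftest import random_instance


def roary_text(rows, genomes=("genomeA", "genomeB")):
    header = ",".join(f'"{c}"' for c in ROARY_META_COLUMNS + tuple(genomes))
    lines = [header]
    for name, cells in rows:
        meta = [name] + [""] * (len(ROARY_META_COLUMNS) - 1)
        lines.append(",".join(f'"{c}"' for c in meta + list(cells)))
    return "\n".join(lines) + "\n"


class TestRoary:
    def test_paralog_cell_splits_into_members(self, tmp_path):
        f = tmp_path / "gpa.csv"
        f.write_text(roary_text([("grpA", ["g1", "h1\th2"])]))
        p = read_roary_csv(f)
        assert p.clusters[0] == {
            GeneId("genomeA", "g1"), GeneId("genomeB", "h1"), GeneId("genomeB", "h2")
        }

    def test_semicolon_separator(self, tmp_path):
        f = tmp_path / "gpa.csv"
        f.write_text(roary_text([("grpA", ["", "h1;h2"])]))
        assert read_roary_csv(f).clusters[0] == {
            GeneId("genomeB", "h1"), GeneId("genomeB", "h2")
        }

    def test_three_rows_three_clusters(self, tmp_path):
        f = tmp_path / "gpa.csv"
        f.write_text(roary_text([
            ("a", ["a1", "b1"]), ("b", ["a2", ""]), ("c", ["", "b3"]),
        ]))
        p = read_roary_csv(f)
        assert p.n_clusters == 3 and p.n_genes == 4

    def test_header_missing_metadata_column_is_format_error(self, tmp_path):
        f = tmp_path / "gpa.csv"
        cols = [c for c in ROARY_META_COLUMNS if c != "No. isolates"] + ["genomeA", "x"]
        f.write_text(",".join(f'"{c}"' for c in cols) + "\n")
        with pytest.raises(FormatError):
            read_roary_csv(f)

    def test_too_few_columns_is_format_error(self, tmp_path):
        f = tmp_path / "gpa.csv"
        f.write_text('"Gene","Annotation","genomeA"\n')
        with pytest.raises(FormatError):
            read_roary_csv(f)

    def test_row_with_no_genes_is_format_error(self, tmp_path):
        f = tmp_path / "gpa.csv"
        f.write_text(roary_text([("empty", ["", ""])]))
        with pytest.raises(FormatError, match="no genes"):
            read_roary_csv(f)

    def test_duplicate_token_across_rows_names_the_token(self, tmp_path):
        f = tmp_path / "gpa.csv"
        f.write_text(roary_text([("a", ["g1", ""]), ("b", ["g1", ""])]))
        with pytest.raises(DuplicateGeneError, match="g1"):
            read_roary_csv(f)


class TestOrthofinder:
    def test_comma_separated_cells(self, tmp_path):
        f = tmp_path / "Orthogroups.tsv"
        f.write_text("Orthogroup\tspA\tspB\nOG0000001\ta1, a2\tb1\n")
        p = read_orthofinder_tsv(f)
        assert p.clusters[0] == {
            GeneId("spA", "a1"), GeneId("spA", "a2"), GeneId("spB", "b1")
        }

    def test_unassigned_genes_become_singletons(self, tmp_path):
        f = tmp_path / "Orthogroups.tsv"
        f.write_text("Orthogroup\tspA\tspB\nOG0000001\ta1\tb1\n")
        u = tmp_path / "Orthogroups_UnassignedGenes.tsv"
        u.write_text("Orthogroup\tspA\tspB\nOG0000002\ta9\t\nOG0000003\t\tb9\n")
        p = read_orthofinder_tsv(f, unassigned_path=u)
        assert p.n_clusters == 3
        assert {GeneId("spA", "a9")} in p.clusters

    def test_empty_orthogroup_row_is_format_error(self, tmp_path):
        f = tmp_path / "Orthogroups.tsv"
        f.write_text("Orthogroup\tspA\nOG0000001\t\n")
        with pytest.raises(FormatError):
            read_orthofinder_tsv(f)

    def test_duplicate_gene_across_orthogroups(self, tmp_path):
        f = tmp_path / "Orthogroups.tsv"
        f.write_text("Orthogroup\tspA\nOG1\ta1\nOG2\ta1\n")
        with pytest.raises(DuplicateGeneError):
            read_orthofinder_tsv(f)


class TestGeneric:
    def test_grouping_in_file_order(self, tmp_path):
        f = tmp_path / "c.tsv"
        f.write_text("c1\tgA|x\nc1\tgA|y\nc2\tgB|x\nc2\tgB|y\n")
        p = read_generic_clusters(f)
        assert [len(c) for c in p.clusters] == [2, 2]
        assert p.cluster_of(GeneId("gA", "x")) == 0

    def test_embedded_token_parsing(self, tmp_path):
        f = tmp_path / "c.tsv"
        f.write_text("c1\tgA|x\n")
        assert GeneId("gA", "x") in read_generic_clusters(f).genes

    def test_bare_token_requires_genome_map(self, tmp_path):
        f = tmp_path / "c.tsv"
        f.write_text("c1\tx\n")
        with pytest.raises(UnknownGenomeError):
            read_generic_clusters(f)
        gm = GenomeMap({"x": "gA"})
        assert GeneId("gA", "x") in read_generic_clusters(f, genome_map=gm).genes

    def test_same_token_in_two_clusters(self, tmp_path):
        f = tmp_path / "c.tsv"
        f.write_text("c1\tgA|x\nc2\tgA|x\n")
        with pytest.raises(DuplicateGeneError):
            read_generic_clusters(f)

    def test_rereading_is_deterministic(self, tmp_path):
        f = tmp_path / "c.tsv"
        f.write_text("c2\tgA|x\nc1\tgB|y\nc2\tgA|z\n")
        p, q = read_generic_clusters(f), read_generic_clusters(f)
        assert p.clusters == q.clusters and p.gene_index == q.gene_index


class TestCogTable:
    def test_reads_assignments_and_skips_blanks(self, tmp_path):
        f = tmp_path / "cog.tsv"
        f.write_text("S|g1\tCOG0001\nS|g2\tCOG0002\nS|g3\t\n")
        cog = read_cog_table(f)
        assert len(cog) == 2
        assert cog.get(GeneId("S", "g3")) is None

    def test_identical_duplicates_deduplicate(self, tmp_path):
        f = tmp_path / "cog.tsv"
        f.write_text("S|g1\tCOG0001\nS|g1\tCOG0001\n")
        assert len(read_cog_table(f)) == 1

    def test_conflicting_duplicate_names_the_gene(self, tmp_path):
        f = tmp_path / "cog.tsv"
        f.write_text("S|g1\tCOG0001\nS|g1\tCOG0009\n")
        with pytest.raises(AnnotationConflictError, match="g1"):
            read_cog_table(f)


def test_genome_map_roundtrip(tmp_path):
    f = tmp_path / "map.tsv"
    f.write_text("x\tgA\ny\tgB\n")
    gm = read_genome_map(f)
    assert gm.resolve("x") == GeneId("gA", "x")
    with pytest.raises(UnknownGenomeError):
        gm.resolve("z")


class TestPresenceAbsence:
    def test_singleton_matrix_rows(self, tmp_path):
        p = PanProfile("p", [{GeneId("a", "1")}, {GeneId("b", "1")}])
        out = tmp_path / "pa.tsv"
        write_presence_absence(p, {"a", "b"}, out)
        lines = out.read_text().splitlines()
        assert lines[0] == "cluster\ta\tb"
        assert lines[1].split("\t")[1:] == ["1", "0"]
        assert lines[2].split("\t")[1:] == ["0", "1"]

    def test_paralogs_counted_individually(self, tmp_path):
        p = PanProfile("p", [{GeneId("a", "1"), GeneId("a", "2")}])
        out = tmp_path / "pa.tsv"
        write_presence_absence(p, {"a"}, out)
        assert out.read_text().splitlines()[1] == "C000001\t2"

    def test_empty_genome_set_errors(self, tmp_path):
        p = PanProfile("p", [{GeneId("a", "1")}])
        with pytest.raises(UsageError):
            write_presence_absence(p, set(), tmp_path / "pa.tsv")


@given(st.integers(0, 10**6))
def test_presence_absence_roundtrip_preserves_occurrence(tmp_path_factory, seed):
    """Occurrences reconstructed from the written matrix equal the
    classifier's occurrences exactly."""
    truth, _, _ = random_instance(seed, n_profiles=1)
    profile, genomes = truth.truth_profile, set(truth.genomes)
    out = tmp_path_factory.mktemp("pa") / "pa.tsv"
    write_presence_absence(profile, genomes, out)
    lines = out.read_text().splitlines()
    occ_from_file = [
        sum(int(v) > 0 for v in line.split("\t")[1:]) for line in lines[1:]
    ]
    occ_expected = [c.occurrence for c in classify_clusters(profile, genomes)]
    assert occ_from_file == occ_expected


@given(st.integers(0, 10**6))
def test_generic_clusters_roundtrip(tmp_path_factory, seed):
    """Writing a profile as a generic TSV and re-reading it reproduces the
    exact partition."""
    truth, _, profiles = random_instance(seed, n_profiles=1)
    p = profiles[0]
    if p.n_clusters == 0:
        return
    out = tmp_path_factory.mktemp("rt") / "clusters.tsv"
    write_generic_clusters(p, out)
    q = read_generic_clusters(out, name=p.name)
    assert q.same_clustering(p)
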