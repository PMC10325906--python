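"""I/O and coordinate-type contracts: parsing, validation, round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epiferro.genomio import (
    CpGSite,
    FormatError,
    GeneModel,
    GenomicInterval,
    MethylomeTrack,
    read_count_table,
    read_genes,
    read_intervals_bed,
    read_methylome_bedgraph,
    write_count_table,
    write_genes,
    write_intervals_bed,
    write_methylome_bedgraph,
)


class TestTypes:
    def test_cpg_site_coverage_from_counts(self):
        s = CpGSite("chr1", 100, 75.0, n_meth=3, n_unmeth=1)
        assert s.coverage == 4

    def test_cpg_site_rejects_inconsistent_counts(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CpGSite("chr1", 100, 10.0, n_meth=3, n_unmeth=1)

    @pytest.mark.parametrize("meth", [-0.1, 100.5])
    def test_cpg_site_rejects_out_of_range_level(self, meth):
        with pytest.raises(ValueError):
            CpGSite("chr1", 100, meth)

    def test_interval_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_single_base_interval_convention(self):
        iv = GenomicInterval("chr1", 100, 101)
        assert len(iv) == 1 and iv.center == 100

    def test_gene_model_requires_strand_and_tss(self):
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", ".", (100,))
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", "+", ())


class TestMethylomeBedgraph:
    def test_counts6_line_parses(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t100\t101\t75.0\t3\t1\n")
        track = read_methylome_bedgraph(p, "counts6")
        site = next(track.sites())
        assert (site.chrom, site.pos, site.meth, site.coverage) == ("chr1", 100, 75.0, 4)

    def test_header_only_file_is_empty_track(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text('track type=bedGraph name="x"\n')
        assert len(read_methylome_bedgraph(p, "level4")) == 0

    def test_level4_has_undefined_coverage(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t100\t101\t75.0\n")
        track = read_methylome_bedgraph(p, "level4")
        assert not track.has_coverage

    @pytest.mark.parametrize("line,pattern", [
        ("chr1\t100\t102\t75.0\t3\t1", "1 bp"),
        ("chr1\t100\t101\t175.0\t3\t1", "outside"),
        ("chr1\tx\t101\t75.0\t3\t1", "malformed"),
        ("chr1\t100\t101\t75.0\t3", "columns"),
    ])
    def test_malformed_lines_name_the_line(self, tmp_path, line, pattern):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t5\t6\t50.0\t1\t1\n" + line + "\n")
        with pytest.raises(FormatError, match=pattern) as exc:
            read_methylome_bedgraph(p, "counts6")
        assert ":2" in str(exc.value)

    def test_identical_duplicates_collapse_conflicting_error(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t100\t101\t75.0\t3\t1\nchr1\t100\t101\t75.0\t3\t1\n")
        assert len(read_methylome_bedgraph(p)) == 1
        p.write_text("chr1\t100\t101\t75.0\t3\t1\nchr1\t100\t101\t50.0\t2\t2\n")
        with pytest.raises(FormatError, match="conflicting"):
            read_methylome_bedgraph(p)

    def test_written_format_contract(self, tmp_path):
        track = MethylomeTrack.from_sites(
            "t", [CpGSite("chr1", 100, 75.0, n_meth=3, n_unmeth=1)]
        )
        p = tmp_path / "t.bedgraph"
        write_methylome_bedgraph(track, p)
        assert p.read_text() == "chr1\t100\t101\t75.000000\t3\t1\n"

    def test_write_read_write_idempotent(self, tmp_path):
        rng = np.random.default_rng(0)
        n = 200
        n_meth = rng.integers(0, 30, n)
        cov = n_meth + rng.integers(1, 30, n)
        pos = np.sort(rng.choice(100_000, size=n, replace=False))
        track = MethylomeTrack.from_arrays(
            "t", ["chr1"] * n, pos, 100.0 * n_meth / cov, n_meth, cov - n_meth
        )
        p1, p2 = tmp_path / "a.bedgraph", tmp_path / "b.bedgraph"
        write_methylome_bedgraph(track, p1)
        write_methylome_bedgraph(read_methylome_bedgraph(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestBed:
    def test_bed4_and_bed3(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr2\t500\t900\tpeakA\nchr3\t1\t2\n")
        ivs = read_intervals_bed(p)
        assert ivs[0] == GenomicInterval("chr2", 500, 900, name="peakA")
        assert ivs[1].strand == "." and ivs[1].name is None

    @pytest.mark.parametrize("line", ["chr1\t900\t500", "chr1\ta\t500"])
    def test_bad_coordinates_rejected(self, tmp_path, line):
        p = tmp_path / "x.bed"
        p.write_text(line + "\n")
        with pytest.raises(FormatError):
            read_intervals_bed(p)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(
        st.tuples(
            st.sampled_from(["chr1", "chr2", "chrX"]),
            st.integers(0, 10_000), st.integers(1, 500),
            st.one_of(st.none(), st.text("abcXYZ_", min_size=1, max_size=6)),
            st.sampled_from(["+", "-", "."]),
        ),
        max_size=30,
    ))
    def test_bed_round_trip(self, tmp_path_factory, rows):
        ivs = [GenomicInterval(c, s, s + w, strand, name)
               for c, s, w, name, strand in rows]
        p = tmp_path_factory.mktemp("bed") / "x.bed"
        write_intervals_bed(ivs, p)
        assert read_intervals_bed(p) == ivs


class TestGenes:
    def test_multi_tss_row(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("Pparg\tchr6\t+\t115000,118500\n")
        (g,) = read_genes(p)
        assert g.tss_list == (115000, 118500)

    @pytest.mark.parametrize("row", [
        "g1\tchr1\t.\t100", "g1\tchr1\t+\t", "g1\tchr1\t+\tx",
    ])
    def test_bad_rows_rejected(self, tmp_path, row):
        p = tmp_path / "g.tsv"
        p.write_text(row + "\n")
        with pytest.raises(FormatError):
            read_genes(p)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("g1\tchr1\t+\t100\ng1\tchr2\t-\t200\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_genes(p)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_random_tables_round_trip_byte_equal(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        genes = [
            GeneModel(
                f"g{i}", f"chr{rng.integers(1, 4)}",
                "+" if rng.random() < 0.5 else "-",
                tuple(sorted(rng.choice(10_000, size=rng.integers(1, 4),
                                        replace=False).tolist())),
            )
            for i in range(20)
        ]
        d = tmp_path_factory.mktemp("genes")
        p1, p2 = d / "a.tsv", d / "b.tsv"
        write_genes(genes, p1)
        write_genes(read_genes(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestCountTable:
    def test_values_and_labels_preserved(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("id\ts1\ts2\nr1\t10\t20\nr2\t30\t40\n")
        m = read_count_table(p)
        assert m.row_ids == ["r1", "r2"] and m.col_ids == ["s1", "s2"]
        assert m.values.tolist() == [[10.0, 20.0], [30.0, 40.0]]

    def test_single_row_table(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("id\ts1\ts2\ts3\nr1\t1\t2\t3\n")
        assert read_count_table(p).shape == (1, 3)

    @pytest.mark.parametrize("body", ["r1\t-1\t2", "r1\tx\t2"])
    def test_bad_counts_rejected(self, tmp_path, body):
        p = tmp_path / "c.tsv"
        p.write_text("id\ts1\ts2\n" + body + "\n")
        with pytest.raises(FormatError):
            read_count_table(p)

    def test_duplicate_row_id_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("id\ts1\nr1\t1\nr1\t2\n")
        with pytest.raises(FormatError, match="duplicated row"):
            read_count_table(p)

    def test_round_trip(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        p1.write_text("id\ts1\ts2\nr1\t10\t20\nr2\t0\t7\n")
        write_count_table(read_count_table(p1), p2, id_header="id")
        assert p1.read_bytes() == p2.read_bytes()
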