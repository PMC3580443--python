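"""Format readers/writers: VCF, site lists, pedigrees, ranked tables."""

import gzip

import pandas as pd
import pytest

import snvsieve as sv
from snvsieve.vcfio import RANKED_COLUMNS, read_ranked_table
from conftest import obs_set, random_cohort, render_vcf

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB
"""


def write_vcf(tmp_path, body, name="test.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestReadVcf:
    def test_empty_vcf(self, tmp_path):
        cohort = sv.read_vcf(write_vcf(tmp_path, ""))
        assert cohort.n_observations == 0
        assert set(cohort.samples) == {"A", "B"}

    def test_crafted_het_record(self, tmp_path):
        body = "1\t1000\t.\tG\tA\t.\tPASS\t.\tGT:AD:DP\t0/1:6,4:10\t0/0:9,0:9\n"
        cohort = sv.read_vcf(write_vcf(tmp_path, body))
        (obs,) = list(cohort.observations())
        assert obs.key == sv.VariantKey("1", 1000, "G", "A")
        assert obs.sample_id == "A"
        assert obs.coverage == 10 and obs.alt_reads == 4
        assert obs.vaf == pytest.approx(0.4)
        assert obs.zygosity == "het"

    def test_multiallelic_split_matches_hand_split(self, tmp_path):
        body = (
            "1\t2000\t.\tC\tA,G\t.\tPASS\t.\tGT:AD:DP\t"
            "1/2:0,5,7:12\t0/1:8,4,0:12\n"
        )
        cohort = sv.read_vcf(write_vcf(tmp_path, body))
        got = {(o.key.alt, o.sample_id, o.alt_reads, o.coverage)
               for o in cohort.observations()}
        # hand split: sample A carries both alts, sample B only the first
        assert got == {("A", "A", 5, 12), ("G", "A", 7, 12), ("A", "B", 4, 12)}

    def test_hom_alt_genotype(self, tmp_path):
        body = "1\t3000\t.\tT\tC\t.\tPASS\t.\tGT:AD:DP\t1/1:0,30:30\t./.:.:.\n"
        cohort = sv.read_vcf(write_vcf(tmp_path, body))
        (obs,) = list(cohort.observations())
        assert obs.zygosity == "hom_alt" and obs.sample_id == "A"

    def test_missing_depth_fields_warn_coverage_zero(self, tmp_path, caplog):
        p = tmp_path / "nodp.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
            "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\n"
        )
        with caplog.at_level("WARNING"):
            cohort = sv.read_vcf(p)
        (obs,) = list(cohort.observations())
        assert obs.coverage == 0
        assert "depth" in caplog.text

    def test_sample_subset(self, tmp_path):
        body = "1\t1000\t.\tG\tA\t.\tPASS\t.\tGT:AD:DP\t0/1:6,4:10\t0/1:5,5:10\n"
        cohort = sv.read_vcf(write_vcf(tmp_path, body), sample_subset=["B"])
        assert {o.sample_id for o in cohort.observations()} == {"B"}
        with pytest.raises(sv.DataError):
            sv.read_vcf(write_vcf(tmp_path, body), sample_subset=["Z"])

    def test_roundtrip_via_rendered_vcf_is_idempotent(self, rng, tmp_path):
        cohort = random_cohort(rng, n_obs=40, with_ann=False)
        # drop "unknown" zygosity: a VCF genotype is always het or hom here
        obs = cohort.obs_frame
        cohort = cohort.replace_observations(
            obs[obs["zygosity"] != "unknown"].reset_index(drop=True)
        )
        p = tmp_path / "render.vcf"
        render_vcf(cohort, p)
        back = sv.read_vcf(p)
        assert obs_set(back) == obs_set(cohort)
        render_vcf(back, tmp_path / "render2.vcf")
        assert (tmp_path / "render2.vcf").read_text() == p.read_text()


class TestReadSites:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert len(sv.read_sites(p, "s")) == 0

    def test_duplicates_collapse(self, tmp_path):
        lines = ["1\t100\tA\tG", "1\t200\tC\tT", "2\t100\tA\tG",
                 "2\t300\tG\tA", "3\t50\tT\tC"]
        p = tmp_path / "sites.tsv"
        p.write_text("\n".join(lines + [lines[0], lines[3]]) + "\n")
        assert len(sv.read_sites(p, "s")) == 5

    def test_alleles_set_within_positions_cross_product(self, tmp_path):
        rows = [f"{c}\t{100 + 10 * i}\t{r}\t{a}"
                for i, (c, r, a) in enumerate(
                    [("1", "A", "G"), ("1", "A", "T"), ("2", "C", "T"),
                     ("2", "G", "A"), ("3", "T", "C"), ("3", "T", "G"),
                     ("4", "A", "C"), ("4", "C", "A"), ("5", "G", "T"),
                     ("5", "T", "A")])]
        p = tmp_path / "ten.tsv"
        p.write_text("\n".join(rows) + "\n")
        alleles = sv.read_sites(p, "a", mode="alleles")
        positions = sv.read_sites(p, "p", mode="positions")
        implied = {
            (c, pos, r, a)
            for (c, pos) in positions.keys
            for r in "ACGT" for a in "ACGT" if r != a
        }
        assert alleles.keys <= implied

    def test_gzip_input(self, tmp_path):
        p = tmp_path / "sites.tsv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("chrom\tpos\tref\talt\n1\t100\tA\tG\n")
        assert len(sv.read_sites(p, "s")) == 1

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("1\t100\tA\tG\n1\tnot_a_pos\tA\tG\n")
        with pytest.raises(sv.DataError, match="line 2"):
            sv.read_sites(p, "s")


class TestReadPedigree:
    def test_trio_links_resolve(self, tmp_path):
        p = tmp_path / "trio.tsv"
        p.write_text(
            "sample\tfather\tmother\tgroup\n"
            "kid\tdad\tmum\tcase\ndad\t-\t-\tparent\nmum\t-\t-\tparent\n"
        )
        metas = sv.read_pedigree(p)
        cohort = sv.Cohort(metas)
        cohort.validate_pedigree()
        assert cohort.samples["kid"].father_id == "dad"

    def test_absent_father_fails_at_assembly(self, tmp_path):
        p = tmp_path / "orphan.tsv"
        p.write_text("sample\tfather\tmother\tgroup\nkid\tdad\tmum\tcase\n")
        cohort = sv.Cohort(sv.read_pedigree(p))
        with pytest.raises(sv.DataError, match="father"):
            cohort.validate_pedigree()

    def test_case_control_groups(self, tmp_path):
        rows = [f"c{i}\t-\t-\tcase" for i in range(4)] + \
               [f"n{i}\t-\t-\tcontrol" for i in range(4)]
        p = tmp_path / "cc.tsv"
        p.write_text("sample\tfather\tmother\tgroup\n" + "\n".join(rows) + "\n")
        metas = sv.read_pedigree(p)
        assert [m.group for m in metas] == ["case"] * 4 + ["control"] * 4
        assert all(m.father_id is None for m in metas)

    def test_duplicate_sample_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("sample\tfather\tmother\tgroup\nx\t-\t-\tcase\nx\t-\t-\tcase\n")
        with pytest.raises(sv.DataError, match="duplicate"):
            sv.read_pedigree(p)


class TestRankedTable:
    def test_empty_table_writes_header_only(self, tmp_path):
        table = sv.rank([])
        p = tmp_path / "empty.tsv"
        sv.write_ranked_table(table, p)
        lines = p.read_text().splitlines()
        assert lines == ["\t".join(RANKED_COLUMNS)]

    def test_published_candidate_table_round_trips(self, tmp_path):
        published = sv.schinzel_giedion_candidates()
        p = tmp_path / "table.tsv"
        sv.write_ranked_table(published, p)
        back = read_ranked_table(p)
        pd.testing.assert_frame_equal(back, published[list(RANKED_COLUMNS)])

    def test_line_count_is_rows_plus_header(self, rng, tmp_path):
        cohort = random_cohort(rng)
        hits = sv.call_hits(cohort, "dominant")
        table = sv.rank(sv.summarize_frame(hits))
        p = tmp_path / "t.tsv"
        sv.write_ranked_table(table, p)
        assert len(p.read_text().splitlines()) == len(table) + 1
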