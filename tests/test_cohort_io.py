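"""Cohort table I/O: validation, orientation and round-trips."""

import numpy as np
import pandas as pd
import pytest

import wlscore as w
from wlscore.errors import ValidationError

from conftest import write_tsv

PANEL_GENES = {
    "BDNF", "CADM2", "FANCL", "FLJ35779", "FTO", "GNPDA2", "HOXC13", "KCTD15",
    "LRP1B", "LRRN6C", "LY86", "MAP2K5", "NFE2L3", "NRXN3", "PRKD1", "RBJ",
    "RPL27A", "RSPO3", "SEC16B", "SH2B1", "TFAP2B", "TMEM18", "TNNI3K",
    "VEGFA", "ZNRF3-KREMEN1",
}

ANN_HEADER = ["rsid", "gene", "risk_allele", "other_allele", "ref_freq", "ref_n"]


class TestAnnotations:
    def test_packaged_panel_has_all_25_loci(self, panel):
        assert len(panel) == 25
        assert {a.gene for a in panel} == PANEL_GENES
        assert len({a.rsid for a in panel}) == 25
        # the published subset of rsIDs, with their genes
        published = {
            "rs13078807": "CADM2", "rs29941": "KCTD15", "rs1294421": "LY86",
            "rs2112347": "FLJ35779", "rs10150332": "NRXN3", "rs4929949": "RPL27A",
            "rs7359397": "SH2B1", "rs9491696": "RSPO3",
        }
        by_id = {a.rsid: a.gene for a in panel}
        for rsid, gene in published.items():
            assert by_id[rsid] == gene

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = write_tsv(tmp_path / "empty.tsv", ANN_HEADER, [])
        assert w.read_annotations(path) == []

    @pytest.mark.parametrize(
        "row,fragment",
        [
            (["rsX", "G", "A", "G", 1.2, 100], "ref_freq"),
            (["rsX", "G", "Z", "G", 0.5, 100], "risk_allele"),
            (["rsX", "G", "A", "A", 0.5, 100], "allele"),
        ],
    )
    def test_malformed_row_error_names_row(self, tmp_path, row, fragment):
        path = write_tsv(tmp_path / "bad.tsv", ANN_HEADER, [row])
        with pytest.raises(ValidationError, match="row 2"):
            w.read_annotations(path)

    def test_duplicate_rsid_rejected(self, tmp_path):
        rows = [["rs1", "G1", "A", "G", 0.5, 100], ["rs1", "G2", "C", "T", 0.5, 100]]
        path = write_tsv(tmp_path / "dup.tsv", ANN_HEADER, rows)
        with pytest.raises(ValidationError, match="duplicate rsid"):
            w.read_annotations(path)


class TestGenotypes:
    def test_read_small_fixture(self, tmp_path, tiny_annotations):
        path = write_tsv(
            tmp_path / "g.tsv",
            ["subject_id", "rs1", "rs2", "rs3"],
            [["s1", 0, 1, 2], ["s2", 2, "NA", 0], ["s3", 1, 1, 1]],
        )
        gm = w.read_genotypes(path, tiny_annotations)
        assert gm.g.shape == (3, 3)
        assert gm.g[0, 2] == 2 and np.isnan(gm.g[1, 1])

    def test_value_out_of_domain_names_cell(self, tmp_path, tiny_annotations):
        path = write_tsv(
            tmp_path / "g.tsv", ["subject_id", "rs1", "rs2", "rs3"], [["s1", 0, 3, 2]]
        )
        with pytest.raises(ValidationError, match="rs2"):
            w.read_genotypes(path, tiny_annotations)

    def test_duplicate_subject_rejected(self, tmp_path, tiny_annotations):
        path = write_tsv(
            tmp_path / "g.tsv",
            ["subject_id", "rs1", "rs2", "rs3"],
            [["s1", 0, 1, 2], ["s1", 1, 1, 1]],
        )
        with pytest.raises(ValidationError, match="duplicate subject"):
            w.read_genotypes(path, tiny_annotations)

    def test_shuffled_columns_read_in_annotation_order(self, tmp_path, tiny_annotations):
        ordered = write_tsv(
            tmp_path / "a.tsv",
            ["subject_id", "rs1", "rs2", "rs3"],
            [["s1", 0, 1, 2], ["s2", 2, 1, 0]],
        )
        shuffled = write_tsv(
            tmp_path / "b.tsv",
            ["subject_id", "rs3", "rs1", "rs2"],
            [["s1", 2, 0, 1], ["s2", 0, 2, 1]],
        )
        a = w.read_genotypes(ordered, tiny_annotations)
        b = w.read_genotypes(shuffled, tiny_annotations)
        assert a.rsids == b.rsids == ["rs1", "rs2", "rs3"]
        np.testing.assert_array_equal(a.g, b.g)

    def test_write_read_round_trip(self, tmp_path, small_cohort):
        gm, _, _ = small_cohort
        path = tmp_path / "rt.tsv"
        w.write_genotypes(gm, path)
        back = w.read_genotypes(path, gm.snvs)
        assert back.subject_ids == gm.subject_ids
        np.testing.assert_array_equal(back.g, gm.g)
        # multiset of entries is preserved
        assert sorted(back.g.ravel()) == sorted(gm.g.ravel())

    def test_unknown_column_dropped_with_warning(self, tmp_path, tiny_annotations):
        path = write_tsv(
            tmp_path / "g.tsv",
            ["subject_id", "rs1", "rs2", "rs3", "rs999"],
            [["s1", 0, 1, 2, 1]],
        )
        with pytest.warns(UserWarning, match="rs999"):
            gm = w.read_genotypes(path, tiny_annotations)
        assert gm.rsids == ["rs1", "rs2", "rs3"]


def _write_vcf(path, annotations, gm, flip=()):
    """Synthesize a VCF from a known risk-count matrix.

    SNVs in ``flip`` put the risk allele in REF (counts complemented);
    otherwise the risk allele is ALT.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.subject_ids),
    ]
    gt_for = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j, ann in enumerate(annotations):
        risk_is_ref = ann.rsid in flip
        ref, alt = (ann.risk_allele, ann.other_allele) if risk_is_ref else (ann.other_allele, ann.risk_allele)
        gts = []
        for v in gm.g[:, j]:
            if np.isnan(v):
                gts.append("./.")
            else:
                alt_count = int(2 - v) if risk_is_ref else int(v)
                gts.append(gt_for[alt_count])
        lines.append(f"1\t{1000 + j}\t{ann.rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n")
    return path


class TestVcfOrientation:
    def test_round_trip_recovers_matrix(self, tmp_path, tiny_annotations):
        g = np.array([[0, 1, 2], [2, np.nan, 0], [1, 2, 1]], dtype=float)
        gm = w.GenotypeMatrix(["s1", "s2", "s3"], tiny_annotations, g)
        path = _write_vcf(tmp_path / "c.vcf", tiny_annotations, gm, flip={"rs2"})
        back = w.orient_vcf(path, tiny_annotations)
        assert back.subject_ids == gm.subject_ids
        np.testing.assert_array_equal(back.g, gm.g)

    @pytest.mark.parametrize("flip,expected", [(set(), 2.0), ({"rs1"}, 2.0)])
    def test_homozygote_orientation(self, tmp_path, tiny_annotations, flip, expected):
        # risk-homozygote is 2 whichever strand carries the risk allele
        gm = w.GenotypeMatrix(["s1"], tiny_annotations, np.array([[2.0, 1.0, 1.0]]))
        path = _write_vcf(tmp_path / "c.vcf", tiny_annotations, gm, flip=flip)
        back = w.orient_vcf(path, tiny_annotations)
        assert back.g[0, 0] == expected
        assert back.g[0, 1] == 1.0  # heterozygote is 1 in either orientation

    def test_multiallelic_site_rejected(self, tmp_path, tiny_annotations):
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1",
            "1\t1000\trs1\tG\tA,T\t.\tPASS\t.\tGT\t0/1",
        ]
        path = tmp_path / "m.vcf"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError, match="multi-allelic"):
            w.orient_vcf(path, tiny_annotations)

    def test_mismatching_alleles_become_missing(self, tmp_path, tiny_annotations):
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1",
            "1\t1000\trs1\tC\tT\t.\tPASS\t.\tGT\t0/1",  # rs1 risk allele is A
        ]
        path = tmp_path / "m.vcf"
        path.write_text("\n".join(lines) + "\n")
        with pytest.warns(UserWarning, match="risk allele"):
            back = w.orient_vcf(path, tiny_annotations)
        assert np.isnan(back.g[0, 0])


PHENO_HEADER = [
    "subject_id", "group", "sex", "age", "height", "baseline_weight",
    "followup_years", "weight_y1", "weight_y2",
]


def _pheno_rows():
    rows = []
    for i in range(8):
        rows.append([f"c{i}", "case", "M" if i % 2 else "F", 50 + i, 1.70,
                     90 + i, 2.0, 88 + i, 89 + i])
    rows.append(["k1", "control", "F", 40, 1.65, 60, "NA", "NA", "NA"])
    rows.append(["k2", "control", "M", 45, 1.80, 75, "NA", "NA", "NA"])
    return rows


class TestPhenotypes:
    def test_fixture_of_10_subjects(self, tmp_path):
        path = write_tsv(tmp_path / "p.tsv", PHENO_HEADER, _pheno_rows())
        table = w.read_phenotypes(path)
        assert len(table.data) == 10
        assert len(table.cases) == 8
        assert set(table.visits["years"]) == {1.0, 2.0}

    def test_control_outside_bmi_window_warns_under_strict_flag(self, tmp_path):
        rows = _pheno_rows()
        rows[-1][5] = 90  # control k2, BMI 27.8
        path = write_tsv(tmp_path / "p.tsv", PHENO_HEADER, rows)
        with pytest.warns(UserWarning, match="k2"):
            w.read_phenotypes(path, strict_bmi=True)

    def test_missing_glucose_columns_load_fine(self, tmp_path):
        path = write_tsv(tmp_path / "p.tsv", PHENO_HEADER, _pheno_rows())
        table = w.read_phenotypes(path)
        assert "glucose_baseline" not in table.data.columns

    def test_case_without_followup_weight_rejected(self, tmp_path):
        rows = _pheno_rows()
        rows[0][7] = "NA"
        rows[0][8] = "NA"
        path = write_tsv(tmp_path / "p.tsv", PHENO_HEADER, rows)
        with pytest.raises(ValidationError, match="c0"):
            w.read_phenotypes(path)

    def test_nonpositive_weight_rejected(self, tmp_path):
        rows = _pheno_rows()
        rows[0][5] = -1
        path = write_tsv(tmp_path / "p.tsv", PHENO_HEADER, rows)
        with pytest.raises(ValidationError, match="baseline weight"):
            w.read_phenotypes(path)

    def test_short_followup_case_rejected(self, tmp_path):
        rows = _pheno_rows()
        rows[0][6] = 0.5
        path = write_tsv(tmp_path / "p.tsv", PHENO_HEADER, rows)
        with pytest.raises(ValidationError, match="followup"):
            w.read_phenotypes(path)

    def test_bare_dot_rejected(self, tmp_path):
        rows = _pheno_rows()
        rows[0][7] = "."
        path = write_tsv(tmp_path / "p.tsv", PHENO_HEADER, rows)
        with pytest.raises(ValidationError, match="'.'"):
            w.read_phenotypes(path)

    def test_phenotype_round_trip(self, tmp_path, small_cohort):
        _, phen, _ = small_cohort
        path = tmp_path / "p.tsv"
        w.write_phenotypes(phen, path)
        back = w.read_phenotypes(path)
        assert len(back.data) == len(phen.data)
        a = phen.visits.sort_values(["subject_id", "years"]).reset_index(drop=True)
        b = back.visits.sort_values(["subject_id", "years"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_exact=False, rtol=1e-9)
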