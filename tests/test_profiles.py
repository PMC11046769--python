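import numpy as np
import pandas as pd
import pytest

from lofclust._exceptions import ValidationError
from lofclust.profiles import (
    VARIANT_COLUMNS,
    build_profiles,
    eligible_genes,
    profile_matrix,
    qc_exclude_nonuniform_background,
    read_variant_table,
)
from lofclust.transcripts import TranscriptModel


def single_exon_model(tid="TX1", gene="G1", L=100):
    return {
        tid: TranscriptModel(
            transcript_id=tid,
            gene_id=gene,
            chrom="chr1",
            strand="+",
            exons=((1, L),),
            cds_genomic_start=1,
            cds_genomic_end=L,
            tier="mane_select",
        )
    }


def vrows(rows):
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def plof_row(pos, gene="G1", tid="TX1", alt="T", cls="plof_snv", ds="population"):
    return (gene, tid, pos, "A", alt, cls, ds)


class TestBuildProfiles:
    def test_counts_and_proportions(self):
        # pLoFs at quintiles (1,1,3,5,5) of an L=100 transcript
        variants = vrows([plof_row(p) for p in (5, 15, 45, 85, 95)])
        prof = build_profiles(variants, single_exon_model())
        row = prof[(prof["class"] == "plof_all") & (prof["dataset"] == "population")]
        assert row[[f"c{i}" for i in range(1, 6)]].values.tolist() == [[2, 0, 1, 0, 2]]
        assert row[[f"p{i}" for i in range(1, 6)]].values.tolist() == [
            [0.4, 0.0, 0.2, 0.0, 0.4]
        ]
        assert int(row["n"].iloc[0]) == 5

    def test_gene_with_no_variants_of_a_class_gets_zero_vector(self):
        variants = vrows([plof_row(5)])
        prof = build_profiles(variants, single_exon_model())
        syn = prof[prof["class"] == "synonymous"].iloc[0]
        assert syn["n"] == 0
        assert all(syn[f"p{i}"] == 0.0 for i in range(1, 6))

    def test_uniform_positions_fill_all_quintiles_evenly(self):
        variants = vrows([plof_row(p) for p in range(5, 100, 10)])
        prof = build_profiles(variants, single_exon_model())
        row = prof[prof["class"] == "plof_all"].iloc[0]
        assert [row[f"c{i}"] for i in range(1, 6)] == [2, 2, 2, 2, 2]

    def test_duplicate_rows_count_once(self):
        variants = vrows([plof_row(5)] * 4 + [plof_row(45)])
        prof = build_profiles(variants, single_exon_model())
        assert int(prof[prof["class"] == "plof_all"]["n"].iloc[0]) == 2

    def test_totals_invariant_under_input_permutation(self):
        rows = [plof_row(p, alt=a) for p in (5, 25, 45) for a in ("T", "G")]
        base = build_profiles(vrows(rows), single_exon_model())
        perm = build_profiles(
            vrows(rows).sample(frac=1, random_state=3), single_exon_model()
        )
        pd.testing.assert_frame_equal(base, perm)

    def test_unknown_transcript_skipped_and_counted(self, caplog):
        variants = vrows([plof_row(5), plof_row(7, tid="TX_UNKNOWN")])
        with caplog.at_level("WARNING"):
            prof = build_profiles(variants, single_exon_model())
        assert prof.attrs["n_rejected"] == 1
        assert "TX_UNKNOWN" in caplog.text
        assert int(prof[prof["class"] == "plof_all"]["n"].iloc[0]) == 1

    def test_snv_sensitivity_mode_drops_indels(self):
        variants = vrows(
            [plof_row(5), plof_row(45, cls="plof_indel", alt="-")]
        )
        prof = build_profiles(
            variants, single_exon_model(), class_mode="snv_sensitivity"
        )
        assert "plof_all" not in set(prof["class"])
        assert int(prof[prof["class"] == "plof_snv"]["n"].iloc[0]) == 1

    def test_position_outside_cds_raises(self):
        variants = vrows([plof_row(101)])
        with pytest.raises(ValidationError, match="TX1"):
            build_profiles(variants, single_exon_model())

    def test_profile_matrix_rows_sum_to_one_or_zero(self, small_profiles):
        X = profile_matrix(small_profiles)
        sums = X.sum(axis=1)
        assert np.all(
            np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-12)
        )


class TestEligibility:
    @staticmethod
    def profile_stub(gene, counts):
        rows = []
        for cls, n in counts.items():
            row = {"gene_id": gene, "class": cls, "dataset": "population", "n": n}
            row.update({f"c{i}": 0 for i in range(1, 6)})
            row.update({f"p{i}": 0.0 for i in range(1, 6)})
            rows.append(row)
        return pd.DataFrame(rows)

    def test_all_classes_at_threshold_is_eligible(self):
        prof = self.profile_stub("G1", {"synonymous": 5, "missense": 5, "plof_all": 5})
        assert eligible_genes(prof) == {"G1"}

    def test_one_class_below_threshold_is_not(self):
        prof = self.profile_stub("G1", {"synonymous": 10, "missense": 10, "plof_all": 4})
        assert eligible_genes(prof) == set()

    def test_empty_profile_list(self):
        assert eligible_genes(self.profile_stub("G1", {}).iloc[0:0]) == set()


class TestBackgroundQc:
    @staticmethod
    def assignment_stub(rows):
        return pd.DataFrame(rows, columns=["gene_id", "class", "role"])

    def test_nonuniform_synonymous_excludes_gene(self):
        a = self.assignment_stub(
            [("G1", "synonymous", "non_uniform"), ("G1", "plof_all", "uniform")]
        )
        assert qc_exclude_nonuniform_background(a) == {"G1"}

    def test_nonuniform_plof_alone_is_retained(self):
        a = self.assignment_stub(
            [
                ("G1", "synonymous", "uniform"),
                ("G1", "missense", "uniform"),
                ("G1", "plof_all", "non_uniform"),
            ]
        )
        assert qc_exclude_nonuniform_background(a) == set()

    def test_all_uniform_gives_empty_exclusion(self):
        a = self.assignment_stub(
            [("G1", "synonymous", "uniform"), ("G2", "missense", "uniform")]
        )
        assert qc_exclude_nonuniform_background(a) == set()


def test_read_variant_table_validates_vocabulary(tmp_path):
    path = tmp_path / "v.tsv"
    df = vrows([plof_row(5)])
    df.loc[0, "consequence_class"] = "nonsense"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(ValidationError, match="nonsense"):
        read_variant_table(path)
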